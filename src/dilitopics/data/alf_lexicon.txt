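# Default acute-liver-failure evidence lexicon (one lowercase phrase per line).
# "fatal/death" is shipped pre-expanded into its two component phrases.
liver failure
hepatic failure
liver transplantation
fatal
death
fulminant hepatitis
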