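Acetaminophen
Amoxicillin/clavulanate
Atorvastatin
Benzbromarone
Carbamazepine
Ciprofloxacin
Cyclophosphamide
Dapsone
Diclofenac
Disulfiram
Doxycycline
Ethambutol
Halothane
Ibuprofen
Isoniazid
Methyldopa
Naproxen
Nefazodone
Nitrofurantoin
Phenytoin
Simvastatin
Sulfamethoxazole/trimethoprim
Sulfasalazine
Tolcapone
Troglitazone
Valproate
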