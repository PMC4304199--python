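drug_id	topic_1	topic_2	topic_3	topic_4	topic_5	topic_6	topic_7	topic_8	topic_9	topic_10	topic_11	topic_12	topic_13	topic_14	topic_15	topic_16	topic_17	topic_18	topic_19	topic_20	topic_21	topic_22	topic_23	topic_24	topic_25	topic_26	topic_27	topic_28	topic_29	topic_30	topic_31	topic_32	topic_33	topic_34	topic_35	topic_36	topic_37	topic_38	topic_39	topic_40
Acetaminophen	0	0	0	1.4E-01	0	1.6E-02	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	3.6E-01	0	0	0	0	0	0	0	4.7E-01	0	0	0
Amoxicillin/clavulanate	0	0	0	1.9E-01	0	0	0	0	0	0	0	0	0	0	1.2E-01	0	0	0	0	6.1E-02	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	6.3E-01	0	0	0
Atorvastatin	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	8.3E-01	0	0	0	0	0	0	3.3E-05	1.7E-01	3.3E-05
Benzbromarone	0	0	0	0	0	0	0	0	0	0	1.4E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	4.4E-01	0	0	0	0	0	0	0	0	4.2E-01	0	0	3.8E-05
Carbamazepine	0	0	4.6E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	3.5E-01	0	0	1.9E-01	0	6.7E-05
Ciprofloxacin	0	0	0	0	0	0	0	0	0	0	0	0	0	2.3E-01	7.7E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2.8E-05	2.8E-05
Cyclophosphamide	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2.9E-01	0	0	0	0	0	0	0	0	0	0	0	6.4E-01	0	0	0	0	0	0	0	5.2E-05	6.2E-02
Dapsone	0	0	0	0	0	0	8.0E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2.0E-01	0	0	0	0	0	0	0	3.3E-05	3.3E-05
Diclofenac	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.4E-01	0	2.2E-02	3.3E-02	0	0	0	0	0	0	0	0	0	0	0	0	0	8.0E-01	0	0	0
Disulfiram	0	0	0	0	0	0	1.6E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2.2E-01	0	0	0	0	0	0	0	0	3.6E-01	2.6E-01	0	0
Doxycycline	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	3.3E-01	0	0	0	0	7.2E-02	0	0	0	0	0	0	0	0	0	0	0	0	0	0	5.9E-01	0	0	3.6E-05
Ethambutol	0	0	0	0	0	0	1.7E-01	0	0	3.5E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	8.7E-02	0	0	0	3.9E-01	0	0	0	0	0	0	0	0	0	0	0	0
Halothane	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	6.5E-03	0	0	0	0	0	0	7.1E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	2.8E-01	0	0	1.6E-05
Ibuprofen	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.3E-01	0	0	0	0	2.9E-01	0	0	0	0	0	0	0	0	0	3.2E-01	0	0	0	0	0	2.0E-01	0	0	0
Isoniazid	0	0	0	0	0	0	0	0	0	9.5E-02	0	0	0	0	0	6.7E-02	0	0	0	0	0	0	1.2E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	6.2E-01	0	0	0
Methyldopa	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2.1E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	7.9E-01	0	5.2E-05	5.2E-05
Naproxen	0	3.6E-02	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.6E-01	0	0	0	0	0	0	0	0	0	1.8E-01	0	0	0	0	0	0	6.2E-01	0	0	0
Nefazodone	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.8E-01	0	2.7E-01	0	1.3E-01	0	0	0	0	0	0	0	0	4.2E-01	0	0	0
Nitrofurantoin	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.0E+00	4.6E-05	4.6E-05	4.6E-05
Phenytoin	0	0	2.1E-01	0	0	0	3.0E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.6E-01	0	2.5E-01	0	0	0
Simvastatin	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.0E-02	0	0	0	0	4.9E-01	0	0	6.1E-02	0	0	4.4E-01	0	0	0
Sulfamethoxazole/trimethoprim	0	0	0	0	0	0	8.3E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1.7E-01	0	0	0	0	0	0	0	0	0	0	3.5E-05	3.5E-05
Sulfasalazine	0	0	0	0	0	0	6.8E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	3.2E-01	0	3.2E-05	3.2E-05
Tolcapone	0	0	8.7E-02	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2.7E-01	0	0	0	0	0	0	0	0	0	0	0	6.4E-01	0	0	3.1E-05
Troglitazone	1.1E-01	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	4.2E-01	0	0	0	0	0	4.6E-01	0	0	2.2E-05
Valproate	0	0	0	0	0	0	0	0	0	0	0	0	0	5.2E-02	0	0	0	0	0	0	0	0	0	0	0	2.1E-01	0	0	0	0	0	0	0	0	4.2E-01	0	0	3.1E-01	0	0
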