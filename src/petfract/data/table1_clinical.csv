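patient,age_sex,stage,medication,iraes,outcome
P1,56/F,baseline,Ipilimumab/Nivolumab,,
P1,56/F,interim,Ipilimumab/Nivolumab,thyroiditis,PMD
P1,56/F,final,Ipilimumab/Nivolumab,colitis,PMD
P2,48/F,baseline,Ipilimumab/Nivolumab,,
P2,48/F,interim,Ipilimumab/Nivolumab,radiopharmaceutical uptake in the injection site,SMD
P2,48/F,final,Ipilimumab/Nivolumab,radiopharmaceutical uptake in the injection site,CMR
P3,60/F,baseline,Ipilimumab/Nivolumab,,
P3,60/F,interim,Ipilimumab/Nivolumab,radiopharmaceutical uptake in the injection site,PMR
P3,60/F,final,Ipilimumab/Nivolumab,thyroiditis; colitis; bone marrow activation,PMR
P4,52/M,baseline,Pembrolizumab,muscle uptake,
P4,52/M,interim,Pembrolizumab,arthritis; muscle uptake,SMD
P4,52/M,final,Pembrolizumab,arthritis,SMD
P5,46/F,baseline,Ipilimumab/Nivolumab,radiopharmaceutical uptake in the injection site,
P5,46/F,interim,Ipilimumab/Nivolumab,duodenitis; muscle uptake,SMD
P5,46/F,final,Ipilimumab/Nivolumab,duodenitis; colitis,PMD
P6,68/M,baseline,Pembrolizumab,,
P6,68/M,interim,Pembrolizumab,,SMD
P6,68/M,final,Pembrolizumab,,PMR
P7,44/F,baseline,Ipilimumab/Nivolumab,,
P7,44/F,interim,Ipilimumab/Nivolumab,colitis; bone marrow activation,PMR
P7,44/F,final,Ipilimumab/Nivolumab,bone marrow activation,PMR
P8,50/F,baseline,Ipilimumab/Nivolumab,laryngeal uptake,
P8,50/F,interim,Ipilimumab/Nivolumab,bone marrow activation,SMD
P8,50/F,final,Ipilimumab/Nivolumab,arthritis; bone marrow activation; radiopharmaceutical uptake in the injection site; muscle uptake,CMR
P9,55/F,baseline,Nivolumab,bone marrow activation,
P9,55/F,interim,Nivolumab,bone marrow activation,SMD
P9,55/F,final,Nivolumab,bone marrow activation,SMD
P10,54/M,baseline,Ipilimumab/Nivolumab,,
P10,54/M,interim,Ipilimumab/Nivolumab,,PMR
P10,54/M,final,Ipilimumab/Nivolumab,,PMR
P11,20/F,baseline,Ipilimumab/Nivolumab,bone marrow activation,
P11,20/F,interim,Ipilimumab/Nivolumab,,PMD
P11,20/F,final,Ipilimumab/Nivolumab,,PMD
P12,84/F,baseline,Pembrolizumab,,
P12,84/F,interim,Pembrolizumab,,SMD
P12,84/F,final,Pembrolizumab,muscle uptake,SMD
P13,53/F,baseline,Nivolumab,bone marrow activation,
P13,53/F,interim,Nivolumab,,SMD
P13,53/F,final,Nivolumab,,SMD
P14,52/M,baseline,Pembrolizumab,laryngeal uptake,
P14,52/M,interim,Pembrolizumab,laryngeal uptake,PMR
P14,52/M,final,Pembrolizumab,laryngeal uptake; radiopharmaceutical uptake in the injection site,PMR
P15,52/M,baseline,Pembrolizumab,,
P15,52/M,interim,Pembrolizumab,,SMD
P15,52/M,final,Pembrolizumab,signs of colitis in descending colon,SMD
P16,71/F,baseline,Ipilimumab/Nivolumab,colon uptake,
P16,71/F,interim,Ipilimumab/Nivolumab,colitis; sarcoid-like mediastinal lymphadenopathy,PMD
P16,71/F,final,Ipilimumab/Nivolumab,colitis,PMD
P17,34/F,baseline,Ipilimumab/Nivolumab,,
P17,34/F,interim,Ipilimumab/Nivolumab,bone marrow activation; colitis; muscle uptake,CMR
P17,34/F,final,Ipilimumab/Nivolumab,brown fat activation,CMR
P18,78/M,baseline,Pembrolizumab,radiopharmaceutical uptake in the injection site,
P18,78/M,interim,Pembrolizumab,arthritis,PMD
P18,78/M,final,Pembrolizumab,,PMD
P19,59/M,baseline,Ipilimumab/Nivolumab,,
P19,59/M,interim,Ipilimumab/Nivolumab,sarcoid-like mediastinal lymphadenopathy; muscle uptake,PMR
P19,59/M,final,Ipilimumab/Nivolumab,sarcoid-like mediastinal lymphadenopathy,PMR
H1,49/M,control,,muscle uptake,
H2,63/M,control,,radiopharmaceutical uptake in the injection site,
H3,39/M,control,,,
H4,61/M,control,,,
H5,52/M,control,,,
H6,63/M,control,,muscle uptake,
H7,69/M,control,,,
H8,60/M,control,,,
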