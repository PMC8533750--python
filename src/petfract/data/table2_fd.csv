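patient,stage,fd,side_effects,outcome,matching
P1,baseline,2.546,,,
P1,interim,2.459,thyroiditis,PMD,YES
P1,final,2.558,colitis,PMD,NO
P2,baseline,2.523,,,
P2,interim,2.515,radiopharmaceutical uptake in the injection site,SMD,YES
P2,final,2.476,radiopharmaceutical uptake in the injection site,CMR,NO
P3,baseline,2.537,,,
P3,interim,2.557,radiopharmaceutical uptake in the injection site,PMR,YES
P3,final,2.527,thyroiditis; colitis; bone marrow activation,PMR,NO
P4,baseline,2.566,muscle uptake,,
P4,interim,2.543,arthritis; muscle uptake,SMD,YES
P4,final,2.543,arthritis,SMD,YES
P5,baseline,2.487,radiopharmaceutical uptake in the injection site,,
P5,interim,2.497,duodenitis; muscle uptake,SMD,YES
P5,final,2.448,duodenitis; colitis,PMD,YES
P6,baseline,2.519,,,
P6,interim,2.530,,SMD,YES
P6,final,2.503,,PMR,NO
P7,baseline,2.542,,,
P7,interim,2.544,colitis; bone marrow activation,PMR,YES
P7,final,2.562,bone marrow activation,PMR,YES
P8,baseline,2.544,laryngeal uptake,,
P8,interim,2.399,bone marrow activation,SMD,NO
P8,final,2.476,arthritis; bone marrow activation; radiopharmaceutical uptake in the injection site; muscle uptake,CMR,NO
P9,baseline,2.524,bone marrow activation,,
P9,interim,2.507,bone marrow activation,SMD,YES
P9,final,2.528,bone marrow activation,SMD,YES
P10,baseline,2.534,,,
P10,interim,2.562,,PMR,YES
P10,final,2.574,,PMR,YES
P11,baseline,2.499,bone marrow activation,,
P11,interim,2.398,,PMD,YES
P11,final,2.474,,PMD,YES
P12,baseline,2.513,,,
P12,interim,2.480,,SMD,NO
P12,final,2.537,muscle uptake,SMD,YES
P13,baseline,2.603,bone marrow activation,,
P13,interim,2.596,,SMD,YES
P13,final,2.590,,SMD,YES
P14,baseline,2.554,laryngeal uptake,,
P14,interim,2.518,laryngeal uptake,PMR,NO
P14,final,2.557,laryngeal uptake; radiopharmaceutical uptake in the injection site,PMR,YES
P15,baseline,2.556,,,
P15,interim,2.604,,SMD,NO
P15,final,2.567,signs of colitis in descending colon,SMD,YES
P16,baseline,2.398,colon uptake,,
P16,interim,2.511,colitis; sarcoid-like mediastinal lymphadenopathy,PMD,NO
P16,final,2.574,colitis,PMD,NO
P17,baseline,2.473,,,
P17,interim,2.518,bone marrow activation; colitis; muscle uptake,CMR,YES
P17,final,2.515,brown fat activation,CMR,YES
P18,baseline,2.541,radiopharmaceutical uptake in the injection site,,
P18,interim,2.523,arthritis hip,PMD,YES
P18,final,2.539,,PMD,YES
P19,baseline,2.549,,,
P19,interim,2.572,sarcoid-like mediastinal lymphadenopathy; muscle uptake,PMR,YES
P19,final,2.580,sarcoid-like mediastinal lymphadenopathy,PMR,YES
H1,control,2.544,muscle uptake,,
H2,control,2.614,radiopharmaceutical uptake in the injection site,,
H3,control,2.623,,,
H4,control,2.496,,,
H5,control,2.646,,,
H6,control,2.518,muscle uptake,,
H7,control,2.581,,,
H8,control,2.589,,,
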