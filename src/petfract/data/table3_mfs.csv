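patient,stage,mfs,delta_d,side_effects,outcome,matching
P1,baseline,2.389,,,,
P1,interim,2.178,-0.211,thyroiditis,PMD,YES
P1,final,2.460,0.071,colitis,PMD,NO
P2,baseline,2.314,,,,
P2,interim,2.281,-0.033,radiopharmaceutical uptake in the injection site,SMD,YES
P2,final,2.523,0.210,radiopharmaceutical uptake in the injection site,CMR,YES
P3,baseline,2.341,,,,
P3,interim,2.358,0.017,radiopharmaceutical uptake in the injection site,PMR,YES
P3,final,2.295,-0.046,thyroiditis; colitis; bone marrow activation,PMR,NO
P4,baseline,2.472,,muscle uptake,,
P4,interim,2.463,-0.009,arthritis; muscle uptake,SMD,YES
P4,final,2.428,-0.044,arthritis,SMD,YES
P5,baseline,2.248,,radiopharmaceutical uptake in the injection site,,
P5,interim,2.485,0.237,duodenitis; muscle uptake,SMD,NO
P5,final,2.202,-0.047,duodenitis; colitis,PMD,YES
P6,baseline,2.450,,,,
P6,interim,2.399,-0.051,,SMD,YES
P6,final,2.252,-0.198,,PMR,NO
P7,baseline,2.309,,,,
P7,interim,2.460,0.151,colitis; bone marrow activation,PMR,YES
P7,final,2.484,0.176,bone marrow activation,PMR,YES
P8,baseline,2.306,,laryngeal uptake,,
P8,interim,2.154,-0.152,bone marrow activation,SMD,NO
P8,final,2.242,-0.064,arthritis; bone marrow activation; radiopharmaceutical uptake in the injection site; muscle uptake,CMR,NO
P9,baseline,2.425,,bone marrow activation,,
P9,interim,2.353,-0.072,bone marrow activation,SMD,YES
P9,final,2.305,-0.120,bone marrow activation,SMD,YES
P10,baseline,2.273,,,,
P10,interim,2.470,0.1907,,PMR,YES
P10,final,2.384,0.111,,PMR,YES
P11,baseline,2.259,,bone marrow activation,,
P11,interim,2.145,-0.115,,PMD,YES
P11,final,2.237,-0.023,,PMD,YES
P12,baseline,2.242,,,,
P12,interim,2.243,0.001,,SMD,YES
P12,final,2.266,0.024,muscle uptake,SMD,YES
P13,baseline,2.394,,bone marrow activation,,
P13,interim,2.466,0.072,,SMD,YES
P13,final,2.461,0.067,,SMD,YES
P14,baseline,2.302,,laryngeal uptake,,
P14,interim,2.511,0.209,laryngeal uptake,PMR,YES
P14,final,2.310,0.008,laryngeal uptake; radiopharmaceutical uptake in the injection site,PMR,YES
P15,baseline,2.233,,,,
P15,interim,2.376,0.143,,SMD,NO
P15,final,2.253,0.020,signs of colitis in descending colon,SMD,YES
P16,baseline,2.155,,colon uptake,,
P16,interim,2.261,0.106,colitis; sarcoid-like mediastinal lymphadenopathy,PMD,NO
P16,final,2.378,0.223,colitis,PMD,NO
P17,baseline,2.192,,,,
P17,interim,2.496,0.303,bone marrow activation; colitis; muscle uptake,CMR,YES
P17,final,2.390,0.198,brown fat activation,CMR,YES
P18,baseline,2.346,,radiopharmaceutical uptake in the injection site,,
P18,interim,2.269,-0.077,arthritis hip,PMD,YES
P18,final,2.413,0.066,,PMD,NO
P19,baseline,2.266,,,,
P19,interim,2.487,0.221,sarcoid-like mediastinal lymphadenopathy; muscle uptake,PMR,YES
P19,final,2.346,0.080,sarcoid-like mediastinal lymphadenopathy,PMR,YES
H1,control,2.560,,muscle uptake,,
H2,control,2.365,,radiopharmaceutical uptake in the injection site,,
H3,control,2.442,,,,
H4,control,2.322,,,,
H5,control,2.538,,,,
H6,control,2.207,,muscle uptake,,
H7,control,2.336,,,,
H8,control,2.479,,,,
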