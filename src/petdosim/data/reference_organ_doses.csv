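organ,mean_mGy_per_MBq,sd_mGy_per_MBq
Adrenals,1.74E-02,3.35E-03
Brain,4.59E-03,6.29E-04
Breasts,5.18E-03,1.84E-03
Gallbladder,2.60E-02,3.77E-03
Lower large intestine,1.52E-02,3.58E-03
Small intestine,1.74E-02,1.48E-03
Stomach,1.54E-02,1.44E-03
Upper large intestine,1.66E-02,7.98E-04
Heart,1.78E-02,1.23E-03
Kidneys,4.36E-02,1.30E-02
Liver,7.06E-02,2.32E-02
Lungs,1.24E-02,1.53E-03
Muscle,8.89E-03,5.55E-04
Ovaries,9.88E-03,1.14E-03
Pancreas,1.86E-02,6.43E-03
Red marrow,1.07E-02,4.84E-04
Cortical bone,1.53E-02,1.73E-03
Spleen,1.18E-02,1.53E-03
Testes,6.81E-03,9.89E-04
Thyroid,8.92E-03,1.10E-03
Urinary bladder,2.17E-02,4.05E-03
Uterus,1.18E-02,1.65E-03
Total Body,1.24E-02,1.27E-04
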