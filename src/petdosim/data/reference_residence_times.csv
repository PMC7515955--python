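organ,male_mean,male_sd,female_mean,female_sd,fed_mean,fed_sd,fasted_mean,fasted_sd
Adrenals,4.27E-04,2.89E-04,5.24E-04,3.11E-04,3.50E-04,1.34E-04,6.01E-04,3.68E-04
Brain,1.26E-02,1.57E-03,1.72E-02,4.68E-03,1.41E-02,4.01E-03,1.57E-02,4.18E-03
Breasts,,,3.72E-03,3.10E-03,1.17E-03,1.84E-03,2.55E-03,3.52E-03
Gallbladder,3.44E-03,1.27E-03,2.71E-03,1.01E-03,3.01E-03,1.16E-03,3.14E-03,1.16E-03
Lower large intestine,7.50E-03,7.68E-03,6.86E-03,2.48E-03,7.67E-03,7.63E-03,6.69E-03,2.57E-03
Small intestine,2.04E-02,7.42E-03,2.44E-02,8.38E-03,1.99E-02,7.61E-03,2.49E-02,7.93E-03
Stomach,8.27E-03,3.10E-03,1.09E-02,4.86E-03,7.46E-03,3.02E-03,1.17E-02,4.30E-03
Upper large intestine,6.98E-03,2.28E-03,9.43E-03,2.11E-03,7.54E-03,2.09E-03,8.88E-03,2.71E-03
Heart,2.24E-02,6.11E-03,2.75E-02,6.36E-03,2.34E-02,5.55E-03,2.65E-02,7.46E-03
Kidneys,4.67E-02,1.07E-02,6.66E-02,2.23E-02,6.06E-02,2.31E-02,5.27E-02,1.56E-02
Liver,4.96E-01,1.24E-01,5.83E-01,2.32E-01,5.98E-01,2.03E-01,4.80E-01,1.57E-01
Lungs,2.48E-02,7.78E-03,3.25E-02,7.45E-03,2.62E-02,4.76E-03,3.10E-02,1.06E-02
Muscle,3.41E-01,5.65E-02,4.44E-01,1.29E-01,3.72E-01,9.29E-02,4.13E-01,1.25E-01
Ovaries,,,1.01E-04,5.17E-05,4.69E-05,1.38E-05,5.42E-05,3.81E-06
Pancreas,2.36E-03,1.08E-03,4.79E-03,4.10E-03,4.31E-03,4.28E-03,2.84E-03,1.22E-03
Red marrow,1.52E-02,3.84E-03,1.86E-02,4.31E-03,1.51E-02,2.45E-03,1.87E-02,5.14E-03
Cortical bone,2.76E-02,3.28E-02,2.02E-02,6.42E-03,1.79E-02,3.83E-03,2.98E-02,3.25E-02
Spleen,3.94E-03,1.05E-03,4.82E-03,1.42E-03,3.96E-03,1.03E-03,4.80E-03,1.45E-03
Testes,7.35E-04,1.39E-04,,,3.13E-04,1.09E-04,4.22E-04,1.47E-04
Thyroid,3.56E-04,8.72E-05,5.16E-04,1.54E-04,4.13E-04,1.42E-04,4.60E-04,1.52E-04
Urinary bladder,2.66E-02,8.70E-03,2.33E-02,7.86E-03,2.72E-02,7.98E-03,2.27E-02,8.31E-03
Uterus,,,2.96E-03,6.57E-04,1.78E-03,5.80E-04,1.18E-03,5.07E-04
Remainder,1.57E+00,2.07E-01,1.34E+00,2.88E-01,1.43E+00,2.99E-01,1.48E+00,2.51E-01
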