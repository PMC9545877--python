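,Ln1,Ln2,Ln3,PHQ1,PHQ2,PHQ3,PHQ4,PHQ5,PHQ6,PHQ7,PHQ8,PHQ9,GAD1,GAD2,GAD3,GAD4,GAD5,GAD6,GAD7
Ln1,0.00,0.31,0.41,0.12,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
Ln2,0.31,0.00,0.51,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.09,0.00,0.00,0.00,0.00,0.00,0.00,0.06
Ln3,0.41,0.51,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05,0.00,0.00,0.00
PHQ1,0.12,0.00,0.00,0.00,0.33,0.00,0.17,0.00,0.00,0.19,0.00,-0.12,0.00,0.00,0.00,0.00,0.00,0.12,0.00
PHQ2,0.00,0.00,0.00,0.33,0.00,0.00,0.12,0.00,0.21,0.00,0.00,0.17,0.22,0.00,0.00,0.00,0.00,0.00,0.00
PHQ3,0.00,0.00,0.00,0.00,0.00,0.00,0.44,0.15,0.00,0.00,0.00,0.07,0.00,0.00,0.00,0.16,0.00,0.00,0.00
PHQ4,0.00,0.00,0.00,0.17,0.12,0.44,0.00,0.15,0.00,0.12,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
PHQ5,0.00,0.00,0.08,0.00,0.00,0.15,0.15,0.00,0.13,0.16,0.00,-0.10,0.00,0.00,0.00,0.00,0.00,0.12,0.00
PHQ6,0.00,0.00,0.00,0.00,0.21,0.00,0.00,0.13,0.00,0.21,0.00,0.43,0.00,0.00,0.18,0.00,-0.10,0.13,0.00
PHQ7,0.00,0.00,0.00,0.19,0.00,0.00,0.12,0.16,0.21,0.00,0.23,0.00,0.00,0.00,0.00,0.13,0.00,0.00,0.00
PHQ8,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.23,0.00,0.39,0.00,0.00,0.00,0.00,0.20,0.00,0.00
PHQ9,0.00,0.09,0.00,-0.12,0.17,0.07,0.00,-0.10,0.43,0.00,0.39,0.00,0.00,0.17,-0.18,-0.11,0.13,0.00,0.00
GAD1,0.00,0.00,0.00,0.00,0.22,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.33,0.21,0.17,0.00,0.00,0.00
GAD2,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.17,0.33,0.00,0.33,0.13,0.00,0.00,0.25
GAD3,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.18,0.00,0.00,-0.18,0.21,0.33,0.00,0.22,0.00,0.00,0.25
GAD4,0.00,0.00,0.05,0.00,0.00,0.16,0.00,0.00,0.00,0.13,0.00,-0.11,0.17,0.13,0.22,0.00,0.45,0.11,0.00
GAD5,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,-0.10,0.00,0.20,0.13,0.00,0.00,0.00,0.45,0.00,0.14,0.00
GAD6,0.00,0.00,0.00,0.12,0.00,0.00,0.00,0.12,0.13,0.00,0.00,0.00,0.00,0.00,0.00,0.11,0.14,0.00,0.24
GAD7,0.00,0.06,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.25,0.25,0.00,0.00,0.24,0.00
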