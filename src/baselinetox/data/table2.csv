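assay,medium,charge_class,a,b,c
PPARgamma (HEK293H),OptiMEM +2 % FBS,anionic,1.25,4.76,0.251
PPARgamma (HEK293H),OptiMEM +2 % FBS,neutral,1.24,5.47,0.235
AREc32 (MCF7),DMEM Glutamax + 10% FBS,anionic,1.22,3.78,0.263
AREc32 (MCF7),DMEM Glutamax + 10% FBS,neutral,1.26,4.43,0.278
AhR (H4IIe),DMEM Glutamax + 10% FBS,anionic,1.22,3.78,0.263
AhR (H4IIe),DMEM Glutamax + 10% FBS,neutral,1.26,4.45,0.277
neurotoxicity (SH-SY5Y),neurobasal medium,anionic,1.22,4.07,0.247
neurotoxicity (SH-SY5Y),neurobasal medium,neutral,1.23,5.61,0.209
generic cell (6% proteins; 0.1% lipids),generic medium (0.3% proteins; 0.001% lipids),anionic,1.22,3.79,0.262
generic cell (6% proteins; 0.1% lipids),generic medium (0.3% proteins; 0.001% lipids),neutral,1.26,4.47,0.275
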