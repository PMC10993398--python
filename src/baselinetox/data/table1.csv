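name,dtxsid,charge_class,ic10_nom_mol_L,ic10_free_mol_L,log_dmedium_w,log_dcell_w,log_dbsa_w,log_dsp_w,log_dlip_w,dlip_predicted,n_fluorinated_carbons,tr_nom,tr_free
PFBA,DTXSID4059916,anionic,3.19E-03,1.78E-03,2.60,2.40,1.94,2.11,1.00,False,3,2.36,3.88
PFHxA,DTXSID3031862,anionic,9.95E-04,4.72E-04,2.78,3.45,2.70,2.45,2.32,False,5,0.49,0.70
PFHpA,DTXSID1037303,anionic,3.75E-04,6.76E-05,3.21,3.69,3.40,2.65,2.91,False,6,0.86,1.26
PFOA,DTXSID8031865,anionic,1.30E-04,1.84E-05,3.67,3.94,3.98,3.14,3.52,False,7,1.32,1.13
PFNA,DTXSID8031863,anionic,9.07E-05,7.72E-06,4.14,3.74,4.39,3.39,4.25,False,8,1.68,0.50
PFUnA,DTXSID8047553,anionic,2.16E-05,3.83E-07,4.74,3.78,4.75,3.97,4.54,False,10,5.04,5.20
HFPO-DA,DTXSID70880215,anionic,6.54E-04,2.20E-04,3.18,3.09,2.28,2.77,2.41,False,5,0.47,1.22
PFHxS,DTXSID3037709,anionic,1.46E-04,4.22E-05,3.14,3.56,3.52,2.95,4.13,False,6,0.17,0.12
PFOS,DTXSID8037706,anionic,4.78E-05,3.89E-06,4.04,4.32,4.52,3.94,4.89,False,8,0.30,0.23
6:2 FTSA,DTXSID6067331,anionic,3.07E-04,4.25E-05,3.45,3.90,3.71,3.39,3.87,True,6,0.25,0.22
PFOSA,DTXSID3038939,partially_charged,7.85E-06,3.28E-07,4.18,3.81,4.33,3.52,4.94,True,8,2.25,2.43
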