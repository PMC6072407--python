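name,charge_type,pka,solubility_ph74,papp_caco2_ph65,vss_per_kg,cl_per_kg,ppb_percent_bound,mol_weight
Chlorpromazine,monobase,9.24,3.72e-4,2.00e-5,10.00,16.00,98.64,318.86
Diazepam,neutral,,1.57e-4,6.03e-5,1.00,0.38,98.61,284.74
Diclofenac,monoacid,4.26,6.53e-3,5.37e-5,0.19,3.83,99.68,296.15
Furosemide,monoacid,3.94,1.78e-1,2.82e-7,0.11,2.19,98.37,330.74
Haloperidol,monobase,8.63,7.56e-5,1.58e-5,17.00,7.80,85.48,375.86
Imipramine,monobase,9.50,9.85e-3,2.75e-5,12.00,13.00,87.87,280.41
Indomethacin,monoacid,4.31,1.44e-3,2.95e-5,0.16,1.61,,357.79
Ketoprofen,monoacid,4.25,5.55e-1,4.68e-5,0.13,1.60,98.73,254.28
Naproxen,monoacid,4.23,9.87e-2,4.68e-5,0.09,0.07,,230.26
Nifedipine,neutral,,5.23e-5,3.24e-5,0.79,7.30,96.17,346.33
Phenytoin,monoacid,8.06,8.51e-5,3.98e-5,1.40,0.57,87.11,252.27
Pindolol,monobase,9.54,2.62e-2,3.89e-5,1.20,7.70,,248.32
Prazosin,monobase,6.50,1.48e-5,4.07e-6,0.73,4.70,96.00,383.40
Trimethoprim,monobase,7.26,2.17e-3,8.71e-5,1.50,2.10,66.10,290.32
Warfarin,monoacid,4.97,3.35e-3,4.37e-5,0.12,0.05,99.31,308.33
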