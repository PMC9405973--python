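# Measured binding parameters of yeast Efl1 constructs and guanine
# nucleotides / Sdo1, transcribed at printed precision from published ITC
# tables.  Kb in mM^-1, dH in kcal mol^-1, dCp (printed, fitted from the
# unrounded enthalpy series of the original analysis) in cal mol^-1 K^-1.
# *_decimals give the printed decimal places of each measured value, used
# to propagate transcription rounding into comparison tolerances.
# Complex key: E = Efl1 R1086Q, ES = Efl1 R1086Q-Sdo1 complex,
# P = Efl1 R1086Q P151L, W = wild-type Efl1, WS = wild-type Efl1-Sdo1.
complex_label,protein,ligand,mg_state,temperature_C,n,Kb_mM,Kb_err_mM,Kb_decimals,dH_kcal,dH_err_kcal,dH_decimals,dCp_printed_cal,dCp_err_cal,source
E:GTP:+Mg,Efl1_R1086Q,GTP,+Mg,25,1,61,7,0,1.04,0.05,2,,,main
E:GTP:+Mg,Efl1_R1086Q,GTP,+Mg,30,1,64,11,0,1.07,0.03,2,10,2,main
E:GTP:+Mg,Efl1_R1086Q,GTP,+Mg,35,1,76,10,0,1.12,0.06,2,,,main
E:GTP:-Mg,Efl1_R1086Q,GTP,-Mg,25,1,60,18,0,1.6,0.3,1,,,main
E:GTP:-Mg,Efl1_R1086Q,GTP,-Mg,30,1,156,34,0,1.7,0.1,1,30,6,main
E:GTP:-Mg,Efl1_R1086Q,GTP,-Mg,35,1,178,28,0,1.9,0.1,1,,,main
E:GDP:+Mg,Efl1_R1086Q,GDP,+Mg,25,1,41,5,0,-3.1,0.1,1,,,main
E:GDP:+Mg,Efl1_R1086Q,GDP,+Mg,30,1,35,7,0,-4.1,0.6,1,-270,40,main
E:GDP:+Mg,Efl1_R1086Q,GDP,+Mg,35,1,34,9,0,-5.8,0.2,1,,,main
E:GDP:-Mg,Efl1_R1086Q,GDP,-Mg,25,1,336,47,0,-6.6,0.2,1,,,main
E:GDP:-Mg,Efl1_R1086Q,GDP,-Mg,30,1,245,37,0,-7.7,0.3,1,-250,17,main
E:GDP:-Mg,Efl1_R1086Q,GDP,-Mg,35,1,226,34,0,-9.1,0.3,1,,,main
P:GTP:+Mg,Efl1_R1086Q_P151L,GTP,+Mg,25,1,55,10,0,-1.7,0.1,1,,,main
P:GTP:+Mg,Efl1_R1086Q_P151L,GTP,+Mg,30,1,59,8,0,-2.5,0.1,1,-220,35,main
P:GTP:+Mg,Efl1_R1086Q_P151L,GTP,+Mg,35,1,54,5,0,-3.9,0.1,1,,,main
E:Sdo1:+Mg,Efl1_R1086Q,Sdo1,+Mg,25,1,256,47,0,-4.3,0.1,1,,,main
E:Sdo1:+Mg,Efl1_R1086Q,Sdo1,+Mg,30,1,288,56,0,-6.3,0.2,1,-440,23,main
E:Sdo1:+Mg,Efl1_R1086Q,Sdo1,+Mg,35,1,543,76,0,-8.7,0.1,1,,,main
ES:GTP:+Mg,Efl1_R1086Q_Sdo1,GTP,+Mg,25,1,34,3,0,-1.1,0.04,1,,,main
ES:GTP:+Mg,Efl1_R1086Q_Sdo1,GTP,+Mg,30,1,17,1,0,-3.0,0.2,1,-400,11,main
ES:GTP:+Mg,Efl1_R1086Q_Sdo1,GTP,+Mg,35,1,19,2,0,-5.1,0.4,1,,,main
ES:GTP:-Mg,Efl1_R1086Q_Sdo1,GTP,-Mg,25,1,57,6,0,-4.0,0.2,1,,,main
ES:GTP:-Mg,Efl1_R1086Q_Sdo1,GTP,-Mg,30,1,44,1,0,-3.9,0.1,1,30,6,main
ES:GTP:-Mg,Efl1_R1086Q_Sdo1,GTP,-Mg,35,1,39,8,0,-3.7,0.4,1,,,main
ES:GDP:+Mg,Efl1_R1086Q_Sdo1,GDP,+Mg,25,1,110,23,0,-2.1,0.08,1,,,main
ES:GDP:+Mg,Efl1_R1086Q_Sdo1,GDP,+Mg,30,1,125,14,0,-3.8,0.05,1,-315,9,main
ES:GDP:+Mg,Efl1_R1086Q_Sdo1,GDP,+Mg,35,1,158,18,0,-5.3,0.11,1,,,main
ES:GDP:-Mg,Efl1_R1086Q_Sdo1,GDP,-Mg,25,1,57,1.5,0,-2.5,0.4,1,,,main
ES:GDP:-Mg,Efl1_R1086Q_Sdo1,GDP,-Mg,30,1,33,5.0,0,-5.4,0.6,1,-550,18,main
ES:GDP:-Mg,Efl1_R1086Q_Sdo1,GDP,-Mg,35,1,29,4.2,0,-8.0,0.8,1,,,main
W:GTP:+Mg,Efl1_WT,GTP,+Mg,30,1,8,0.7,0,-6.4,0.4,1,-560,23,wild_type_ref
W:GTP:-Mg,Efl1_WT,GTP,-Mg,30,1,4,0.3,0,-7.3,0.3,1,-700,34,wild_type_ref
W:GDP:+Mg,Efl1_WT,GDP,+Mg,30,1,27,3,0,-5.6,0.2,1,-310,5,wild_type_ref
W:GDP:-Mg,Efl1_WT,GDP,-Mg,30,1,64,9,0,-6.7,0.3,1,-318,35,wild_type_ref
W:Sdo1:+Mg,Efl1_WT,Sdo1,+Mg,30,1,3110,630,0,-13.4,0.4,1,-860,31,wild_type_ref
WS:GTP:-Mg,Efl1_WT_Sdo1,GTP,-Mg,30,1,89,12,0,-2.1,0.2,1,-90,5,wild_type_ref
WS:GDP:-Mg,Efl1_WT_Sdo1,GDP,-Mg,30,1,19,1,0,-7.4,0.0,1,-640,34,wild_type_ref
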