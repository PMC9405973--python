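# Heterotropic cooperativity edges: each row divides the association
# constant of the numerator complex by that of the denominator complex at
# every temperature shared by both series.
effect_label,group,numerator_label,denominator_label
Mg on GTP (Sdo1-bound),Mg_effect,ES:GTP:+Mg,ES:GTP:-Mg
Mg on GDP (Sdo1-bound),Mg_effect,ES:GDP:+Mg,ES:GDP:-Mg
Mg on GTP,Mg_effect,E:GTP:+Mg,E:GTP:-Mg
Mg on GDP,Mg_effect,E:GDP:+Mg,E:GDP:-Mg
Sdo1 on MgGTP,Sdo1_effect,ES:GTP:+Mg,E:GTP:+Mg
Sdo1 on MgGDP,Sdo1_effect,ES:GDP:+Mg,E:GDP:+Mg
Sdo1 on GTP,Sdo1_effect,ES:GTP:-Mg,E:GTP:-Mg
Sdo1 on GDP,Sdo1_effect,ES:GDP:-Mg,E:GDP:-Mg
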