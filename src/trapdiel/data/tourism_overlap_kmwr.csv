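unit,kind,n_present,n_absent,delta,ci_lo,ci_hi,u2
Southern collared peccary,species,111,89,0.86,0.77,0.92,0.06
White-nosed coati,species,37,43,0.82,0.68,0.92,0.08
Central American agouti,species,39,41,0.79,0.65,0.90,0.06
White-tailed deer,species,22,27,0.72,0.56,0.86,0.05
Whole community,group,234,241,0.90,0.84,0.94,0.07
Diurnal species,group,210,204,0.89,0.82,0.93,0.08
Nocturnal species,group,27,27,0.78,0.62,0.91,0.07
Herbivores,group,177,163,0.88,0.81,0.93,0.05
Omnivores and carnivores,group,64,71,0.78,0.67,0.88,0.07
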