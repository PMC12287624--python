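herbivore,body_mass_kg,life_stage,N,P,K,Ca,Mg,Na,N:P,Ca:P,K:Na
cattle,600,lactating,1.71,0.21,0.69,0.51,0.21,0.12,6-8,,1-5
cattle,600,non_lactating,1.40,0.16,0.58,0.27,0.18,0.09,,,
wildebeest,143,lactating,,0.39,,0.34,,0.05,,1-2,
wildebeest,143,non_lactating,,0.19,,0.12,,0.04,,,
sheep,75,lactating,2.24,0.32,0.30,0.28,0.14,0.08,,,
sheep,75,non_lactating,1.78,0.11,0.30,0.14,0.11,0.07,,,
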