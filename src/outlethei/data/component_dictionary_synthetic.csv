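canonical,cycle,source_column
total_fruits,*,total_fruits
whole_fruits,*,whole_fruits
total_vegetables,*,total_vegetables
greens_and_beans,*,greens_and_beans
whole_grains,*,whole_grains
refined_grains,*,refined_grains
dairy,*,dairy
total_protein,*,total_protein
seafood_plant_protein,*,seafood_plant_protein
mufa_g,*,mufa_g
pufa_g,*,pufa_g
sfa_g,*,sfa_g
sodium_mg,*,sodium_mg
added_sugars_tsp,*,added_sugars_tsp
energy_kcal,*,energy_kcal
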