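component,max_points,direction,unit,source,scale,kcal_per_unit,max_score_at,zero_score_at
total_fruits,5,adequacy,per_1000kcal,total_fruits,1,,0.8,0.0
whole_fruits,5,adequacy,per_1000kcal,whole_fruits,1,,0.4,0.0
total_vegetables,5,adequacy,per_1000kcal,total_vegetables,1,,1.1,0.0
greens_and_beans,5,adequacy,per_1000kcal,greens_and_beans,1,,0.2,0.0
whole_grains,10,adequacy,per_1000kcal,whole_grains,1,,1.5,0.0
dairy,10,adequacy,per_1000kcal,dairy,1,,1.3,0.0
total_protein_foods,5,adequacy,per_1000kcal,total_protein,1,,2.5,0.0
seafood_plant_proteins,5,adequacy,per_1000kcal,seafood_plant_protein,1,,0.8,0.0
fatty_acids,10,ratio,fat_ratio,,1,,2.5,1.2
refined_grains,10,moderation,per_1000kcal,refined_grains,1,,1.8,4.3
sodium,10,moderation,per_1000kcal,sodium_mg,0.001,,1.1,2.0
added_sugars,10,moderation,percent_energy,added_sugars_tsp,1,16,6.5,26.0
saturated_fats,10,moderation,percent_energy,sfa_g,1,9,8.0,16.0
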