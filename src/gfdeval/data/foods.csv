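# gfdeval-food-schema v1
food_id,name,senc_group,nova_group,is_gfp,gfp_category,energy_kcal_100g,protein_g_100g,carb_g_100g,sugars_g_100g,lipid_g_100g,sfa_g_100g,fibre_g_100g,cholesterol_mg_100g,standard_portion_g,fructose_g_100g,glucose_g_100g,lactose_g_100g,sorbitol_g_100g,mannitol_g_100g,raffinose_g_100g,stachyose_g_100g,total_fructan_g_100g,inulin_g_100g,fructan_source
milk_whole,Whole milk,dairy,G1,False,none,63.6,3.1,4.7,4.7,3.6,2.3,0.0,14,200,0,0.1,4.7,0,0,0,0,0,0,fsanz
milk_semi,Semi-skimmed milk,dairy,G1,False,none,46.4,3.2,4.8,4.8,1.6,1.0,0.0,8,200,0,0,4.8,0,0,0,0,0,0,fsanz
yogurt_plain,Plain yogurt,dairy,G3,False,none,60.2,3.8,4.5,4.5,3.0,1.9,0.0,11,125,0,0.3,4.0,0,0,0,0,0,0,fsanz
cheese_semicured,Semi-cured cheese,dairy,G3,False,none,367.0,25.0,1.5,0.5,29.0,18.0,0.0,95,40,0,0,0.5,0,0,0,0,0,0,fsanz
dairy_dessert,Chocolate dairy dessert,dairy,G4,False,none,135.5,3.5,20.0,17.5,4.5,3.0,0.5,12,125,1.5,2.0,3.8,0,0,0,0,0,0,fsanz
rice_white,White rice (raw),cereals,G1,False,none,350.9,7.0,78.0,0.3,0.9,0.2,1.4,0,70,0,0,0,0,0,0,0,0.2,0,own_cereal_assay
corn_grain,Sweet corn,cereals,G1,False,none,107.2,3.3,19.0,3.2,1.4,0.2,2.7,0,140,1.2,1.6,0,0.3,0,0,0,0.3,0,own_cereal_assay
quinoa,Quinoa (raw),cereals,G1,False,none,364.0,14.0,60.0,2.0,6.0,0.7,7.0,0,60,0,0,0,0,0,0,0,0.4,0,own_cereal_assay
oats_gf,Gluten-free oat flakes,cereals,G1,False,none,369.0,13.5,58.0,1.0,7.0,1.2,10.0,0,40,0,0,0,0,0,0,0,0.6,0,own_cereal_assay
gf_bread,Gluten-free bread,cereals,G4,True,bread,273.0,4.5,47.0,3.0,6.0,0.9,6.5,0,60,0.7,0.9,0,0,0,0,0,0.8,0.5,own_cereal_assay
gf_pasta,Gluten-free pasta (raw),cereals,G4,True,pasta,355.0,6.5,76.0,1.2,2.0,0.4,3.5,0,80,0,0,0,0,0,0,0,0.5,0,own_cereal_assay
gf_breakfast_cereal,Gluten-free breakfast cereals,cereals,G4,True,breakfast_cereals,379.0,6.0,80.0,22.0,3.0,1.0,4.0,0,30,1.5,1.8,0,0,0,0,0,0.9,0,own_cereal_assay
gf_cookies,Gluten-free cookies,cereals,G4,True,cookies,453.0,5.5,68.0,24.0,17.0,8.0,3.0,25,30,1.0,1.2,0,0,0,0,0,0.7,0,own_cereal_assay
gf_pizza,Gluten-free pizza base,cereals,G4,True,pizza,317.0,7.5,50.0,3.5,9.0,3.5,3.0,10,150,0.8,0.9,0,0,0,0,0,0.6,0,own_cereal_assay
gf_cereal_bar,Gluten-free cereal bar,cereals,G4,True,cereal_bars,403.0,6.0,70.0,30.0,10.0,4.0,4.5,0,25,,,,,,,,,,unknown
gf_cake,Gluten-free sponge cake,pastries,G4,True,cake_scone_bun_biscuit,406.0,5.0,55.0,30.0,18.0,5.5,2.0,80,60,2.0,2.2,0,0,0,0,0,0.4,0,own_cereal_assay
gf_crepe,Gluten-free crepe,cereals,G4,True,fajita_crepe_pancake,238.0,6.5,32.0,8.0,9.0,3.0,1.5,60,50,0,0,1.2,0,0,0,0,0.3,0,own_cereal_assay
gf_muffin,Gluten-free muffin,pastries,G4,True,other,405.0,5.0,50.0,26.0,20.0,4.5,2.5,70,55,1.8,2.0,0,0,0,0,0,0.4,0,own_cereal_assay
tomato,Tomato,vegetables,G1,False,none,22.2,0.9,3.5,2.6,0.2,0.05,1.4,0,120,1.4,1.2,0,0,0,0,0,0.2,0,literature_plant
lettuce,Lettuce,vegetables,G1,False,none,15.2,1.2,1.4,0.8,0.2,0.03,1.5,0,80,0.5,0.4,0,0,0,0,0,0.1,0,literature_plant
onion,Onion,vegetables,G1,False,none,38.2,1.2,7.0,4.2,0.2,0.04,1.8,0,60,1.3,1.9,0,0,0,0,0,1.8,1.1,literature_plant
carrot,Carrot,vegetables,G1,False,none,38.4,0.9,6.8,4.5,0.2,0.04,2.9,0,100,1.0,1.2,0,0,0,0,0,0.3,0,literature_plant
green_beans,Green beans,vegetables,G1,False,none,32.9,1.9,4.2,1.9,0.3,0.06,2.9,0,150,1.2,1.1,0,0.4,0,0,0,0.2,0,literature_plant
artichoke,Artichoke,vegetables,G1,False,none,44.4,2.9,5.0,1.0,0.2,0.05,5.5,0,120,0.4,0.3,0,0,0,0,0,4.5,3.0,literature_plant
potato,Potato,vegetables,G1,False,none,80.9,2.1,17.0,0.8,0.1,0.03,1.8,0,180,0.2,0.3,0,0,0,0,0,0.1,0,literature_plant
mushroom,Mushroom,vegetables,G1,False,none,23.7,3.1,1.0,0.6,0.3,0.05,2.3,0,100,0,0,0,0,1.5,0,0,0.1,0,literature_plant
apple,Apple,fruits,G1,False,none,55.4,0.3,12.0,10.5,0.2,0.03,2.2,0,150,5.9,2.4,0,0.5,0,0,0,0.1,0,literature_plant
pear,Pear,fruits,G1,False,none,58.1,0.4,12.5,10.0,0.1,0.02,2.8,0,160,6.2,2.6,0,2.0,0,0,0,0.1,0,literature_plant
banana,Banana,fruits,G1,False,none,95.9,1.1,21.0,17.0,0.3,0.1,2.4,0,120,4.9,5.0,0,0,0,0,0,0.5,0.3,literature_plant
orange,Orange,fruits,G1,False,none,45.4,0.9,9.0,8.3,0.2,0.03,2.0,0,180,2.5,2.3,0,0,0,0,0,0.1,0,literature_plant
grapes,Grapes,fruits,G1,False,none,72.9,0.6,16.5,15.5,0.3,0.1,0.9,0,100,8.1,7.9,0,0,0,0,0,0.0,0,literature_plant
watermelon,Watermelon,fruits,G1,False,none,35.0,0.6,7.5,7.0,0.2,0.02,0.4,0,200,3.4,1.6,0,0,0.3,0,0,0.2,0,literature_plant
olive_oil,Olive oil,oils,G2,False,none,900.0,0.0,0.0,0.0,100.0,14.0,0.0,0,10,0,0,0,0,0,0,0,0,0,fsanz
sunflower_oil,Sunflower oil,oils,G2,False,none,900.0,0.0,0.0,0.0,100.0,11.0,0.0,0,10,0,0,0,0,0,0,0,0,0,fsanz
butter,Butter,oils,G3,False,none,743.2,0.7,0.6,0.6,82.0,52.0,0.0,230,12,0,0,0.6,0,0,0,0,0,0,fsanz
chicken_breast,Chicken breast,meat,G1,False,none,108.0,22.5,0.0,0.0,2.0,0.6,0.0,70,125,0,0,0,0,0,0,0,0,0,fsanz
beef_lean,Lean beef,meat,G1,False,none,136.0,20.5,0.0,0.0,6.0,2.5,0.0,60,125,0,0,0,0,0,0,0,0,0,fsanz
pork_loin,Pork loin,meat,G1,False,none,156.0,21.0,0.0,0.0,8.0,2.9,0.0,65,125,0,0,0,0,0,0,0,0,0,fsanz
serrano_ham,Serrano ham,meat,G3,False,none,241.0,30.5,0.5,0.1,13.0,4.5,0.0,70,50,0,0,0,0,0,0,0,0,0,fsanz
sausage_gf,Gluten-free sausage,meat,G4,False,none,307.0,13.0,3.0,0.8,27.0,10.0,0.0,60,80,,,,,,,,,,unknown
hake,Hake,fish,G1,False,none,87.8,17.0,0.0,0.0,2.2,0.4,0.0,50,140,0,0,0,0,0,0,0,0,0,fsanz
salmon,Salmon,fish,G1,False,none,188.0,20.0,0.0,0.0,12.0,2.5,0.0,55,140,0,0,0,0,0,0,0,0,0,fsanz
tuna_canned,Canned tuna in oil,fish,G3,False,none,204.0,24.0,0.0,0.0,12.0,1.9,0.0,50,60,0,0,0,0,0,0,0,0,0,fsanz
egg,Hen egg,eggs,G1,False,none,151.8,12.5,0.7,0.7,11.0,3.3,0.0,385,110,0,0,0,0,0,0,0,0,0,fsanz
chickpeas,Chickpeas (raw),legumes,G1,False,none,335.5,19.5,44.5,2.4,5.5,0.6,15.0,0,70,0,0,0,0,0,0.6,1.7,0.6,0,literature_pulse
lentils,Lentils (raw),legumes,G1,False,none,322.5,23.5,48.0,1.8,1.5,0.2,11.5,0,70,0,0,0,0,0,0.4,1.9,0.5,0,literature_pulse
white_beans,White beans (raw),legumes,G1,False,none,316.5,21.0,46.0,2.1,1.5,0.3,17.5,0,70,0,0,0,0,0,0.5,2.6,0.7,0,literature_pulse
almonds,Almonds,nuts,G1,False,none,598.0,20.0,7.0,4.0,52.0,4.0,11.0,0,25,0,0,0,0,0,0.6,0,0.4,0,literature_plant
walnuts,Walnuts,nuts,G1,False,none,666.0,14.5,7.0,2.6,63.0,6.0,6.5,0,25,0,0,0,0,0,0,0,0.2,0,literature_plant
dark_chocolate,Dark chocolate,pastries,G4,False,none,532.0,6.0,46.0,40.0,34.0,20.0,9.0,3,20,,,,,,,,,,unknown
sugar,White sugar,other,G2,False,none,400.0,0.0,100.0,100.0,0.0,0.0,0.0,0,8,0.0,0.0,0,0,0,0,0,0,0,fsanz
honey,Honey,other,G2,False,none,321.6,0.4,80.0,80.0,0.0,0.0,0.0,0,15,40.0,33.0,0,0,0,0,0,0,0,fsanz
soft_drink,Sugared soft drink,other,G4,False,none,42.0,0.0,10.5,10.5,0.0,0.0,0.0,0,330,5.8,4.5,0,0,0,0,0,0,0,fsanz
jam,Fruit jam,other,G3,False,none,244.5,0.4,60.0,57.0,0.1,0.02,1.0,0,20,18.0,14.0,0,0.3,0,0,0,0,0,fsanz
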