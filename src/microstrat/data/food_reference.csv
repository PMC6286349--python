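food,group,health_value,base_daily,protein_g,fat_g,carb_g,fibre_g,kcal
whole_milk,dairy,0.70,1.20,6.8,7.0,9.4,0.0,127.8
skimmed_milk,dairy,0.75,0.60,6.8,0.6,9.8,0.0,71.8
yoghurt_fullfat,dairy,0.65,0.50,5.0,4.5,6.2,0.0,85.3
yoghurt_skimmed,dairy,0.72,0.30,5.4,0.5,7.0,0.0,54.1
cheese,dairy,0.45,0.60,7.5,9.9,0.4,0.0,120.7
eggs,protein,0.60,0.40,6.3,5.3,0.4,0.0,74.5
fish,protein,0.90,0.30,18.0,5.0,0.0,0.0,117.0
fried_fish,protein,0.40,0.15,14.0,12.0,8.0,0.4,196.0
chicken,protein,0.65,0.40,21.0,6.0,0.0,0.0,138.0
red_meat,protein,0.40,0.35,20.0,12.0,0.0,0.0,188.0
ham,protein,0.30,0.40,9.0,3.0,0.5,0.0,65.0
sausages,protein,0.15,0.35,8.0,16.0,2.0,0.0,184.0
salami,protein,0.15,0.20,7.0,12.0,0.5,0.0,138.0
wholemeal_bread,grain,0.90,1.00,4.0,1.0,18.0,3.2,97.0
white_bread,grain,0.40,1.20,3.6,0.9,21.0,1.0,106.5
breakfast_cereal,grain,0.60,0.50,3.0,1.0,25.0,2.5,121.0
sweetened_cereal,grain,0.25,0.40,2.2,1.5,28.0,1.2,134.3
porridge_oats,grain,0.90,0.35,4.5,2.5,24.0,3.5,136.5
pasta,grain,0.55,0.60,5.5,1.0,32.0,1.8,159.0
rice,grain,0.55,0.45,3.8,0.5,30.0,0.8,139.7
potatoes_boiled,vegetable,0.65,0.60,2.5,0.2,20.0,2.0,91.8
chips_fries,snack,0.15,0.35,3.0,12.0,30.0,2.5,240.0
crisps,snack,0.10,0.30,1.8,10.0,15.0,1.2,157.2
pizza,snack,0.20,0.30,9.0,10.0,33.0,2.0,258.0
burgers,snack,0.20,0.20,13.0,14.0,25.0,1.5,278.0
vegetables_cooked,vegetable,1.00,1.00,2.0,0.3,7.0,3.0,38.7
raw_vegetables,vegetable,1.00,0.80,1.5,0.2,5.0,2.5,27.8
legumes,vegetable,0.95,0.30,8.0,0.8,18.0,6.5,111.2
fresh_fruit,fruit,1.00,1.30,0.8,0.3,14.0,2.4,61.9
dried_fruit,fruit,0.70,0.20,1.0,0.2,25.0,3.0,105.8
nuts,snack,0.85,0.20,6.0,15.0,5.0,2.5,179.0
seeds,snack,0.90,0.15,5.5,13.0,4.0,3.0,155.0
fruit_juice,drink,0.45,0.70,0.5,0.1,11.0,0.2,46.9
sweetened_drinks,drink,0.05,0.80,0.0,0.0,11.0,0.0,44.0
diet_drinks,drink,0.30,0.30,0.0,0.0,0.3,0.0,1.2
water,drink,1.00,3.00,0.0,0.0,0.0,0.0,0.0
chocolate,sweet,0.20,0.45,2.0,8.0,15.0,1.0,140.0
candy_sweets,sweet,0.05,0.50,0.0,0.2,18.0,0.0,73.8
biscuits_cookies,sweet,0.20,0.60,1.5,5.0,17.0,0.6,119.0
cake,sweet,0.20,0.30,2.5,9.0,25.0,0.8,191.0
ice_cream,sweet,0.25,0.30,2.0,6.5,15.0,0.2,126.5
honey,sweet,0.55,0.20,0.1,0.0,17.0,0.0,68.4
jam,sweet,0.35,0.25,0.1,0.0,14.0,0.2,56.4
butter,fat,0.30,0.40,0.1,8.1,0.1,0.0,73.7
margarine,fat,0.35,0.30,0.0,7.0,0.1,0.0,63.4
olive_oil,fat,0.80,0.30,0.0,9.0,0.0,0.0,81.0
ketchup_sauces,condiment,0.30,0.40,0.3,0.1,6.0,0.1,26.1
mayonnaise,condiment,0.20,0.20,0.2,11.0,0.6,0.0,102.2
snack_bars,snack,0.35,0.25,1.5,4.0,18.0,1.0,114.0
savoury_pastries,snack,0.20,0.25,4.0,11.0,22.0,1.0,203.0
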