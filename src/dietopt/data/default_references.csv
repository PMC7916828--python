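nutrient_id,lower,upper,unit,basis,energy_factor,qualifying,disqualifying,source_tag
protein,57,,g,absolute,,True,False,RNI
fiber,27.5,,g,absolute,,True,False,AI
epa_dha,250,,mg,absolute,,True,False,AI
vitamin_a,700,3000,ug,absolute,,True,False,RNI+UL
vitamin_d,15,100,ug,absolute,,True,False,AI+UL
vitamin_e,12,300,mg,absolute,,True,False,AI+UL
vitamin_k,70,,ug,absolute,,True,False,AI
thiamin,1.05,,mg,absolute,,True,False,RNI
riboflavin,1.6,,mg,absolute,,True,False,RNI
niacin,15.1,,mg,absolute,,True,False,RNI
pantothenic_acid,5,,mg,absolute,,True,False,AI
vitamin_b6,1.65,25,mg,absolute,,True,False,RNI+UL
folate,330,1000,ug,absolute,,True,False,RNI+UL
vitamin_b12,4,,ug,absolute,,True,False,AI
vitamin_c,102.5,,mg,absolute,,True,False,RNI
biotin,40,,ug,absolute,,True,False,AI
calcium,950,2500,mg,absolute,,True,False,RNI+UL
phosphorus,550,,mg,absolute,,True,False,AI
magnesium,325,,mg,absolute,,True,False,AI
iron,13.5,,mg,absolute,,True,False,RNI
zinc,10.2,25,mg,absolute,,True,False,RNI+UL
copper,1.45,5,mg,absolute,,True,False,AI+UL
selenium,70,300,ug,absolute,,True,False,AI+UL
iodine,150,600,ug,absolute,,True,False,AI+UL
potassium,3500,,mg,absolute,,True,False,AI
manganese,3,,mg,absolute,,True,False,AI
total_fat,,30,pct_energy,percent_of_energy,9,False,True,MRV
saturated_fat,,10,pct_energy,percent_of_energy,9,False,True,MRV
trans_fat,,1,pct_energy,percent_of_energy,9,False,True,MRV
added_sugars,,10,pct_energy,percent_of_energy,4,False,True,MRV
cholesterol,,300,mg,absolute,,False,True,MRV
sodium,,2000,mg,absolute,,False,True,MRV
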