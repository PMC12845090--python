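# Synthetic global reference statistics (NON-AUTHORITATIVE)
# source: global
id,mean,sd
whole_grains,112.20651250813425,52.96108683549367
refined_grains,362.3718855266863,158.31350463193235
legumes,63.50367398652797,27.625687421968205
nuts_seeds,23.27399679944726,10.515030956176062
vegetable_oils,22.553455427883993,11.922346526080082
olive_oil,9.55215649847575,6.020608113635778
butter,11.447663424945834,6.697844401382136
hydrogenated_fats,13.814026895515301,8.732239139679635
soft_drinks,115.74264606870642,70.98523753764255
coffee,90.52984048384407,48.11726991916931
tea,455.3666839346237,246.47948046256496
processed_foods,82.45912874406929,43.446680179836946
sweets,63.08202475864877,29.745848708660183
salt,9.106508966204578,5.133923493708656
fruits,327.29609856197726,142.50599353360434
vegetables,417.70566019582446,175.07502276841024
red_meat,51.839365669131844,30.249826050409514
processed_meat,14.336007750830685,9.0430456823448
white_meat,62.56472033294606,33.87394205356215
fish,29.105513716407856,17.63363737391066
dairy_high_fat,113.15420450857631,61.8723473938053
dairy_low_fat,173.04907736390695,95.95236059585686
eggs,34.286382386674674,18.569028378241562
diet_drinks,34.45801787364252,19.17507249082339
alcoholic_drinks,5.752549053916681,3.204739359910316
vitamin_c,103.0693423547707,58.54335277384896
vitamin_e,13.93262605637042,7.8802301724651045
vitamin_a,0.9244878419941706,0.5322181067812005
folate,0.405857791651812,0.23495969899045982
zinc,11.522438454599877,6.62498023461921
selenium,0.06946699043753611,0.03919847624697391
magnesium,371.0355903947457,212.0200073806794
calcium,1035.6250495648849,593.0397850461446
iron,16.399428903812144,9.83465562958147
polyphenols,1043.48450611071,650.6358365339078
carotenoids,14.054432100785418,8.584746446467838
phytosterols,293.8716988614753,178.79845998991183
flavonoids,351.1095480704502,213.74908133432695
fiber,26.209462591921938,16.754426825429675
omega3,1.732460991375463,0.9801369808123056
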