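# NON-AUTHORITATIVE example coefficients (synthetic illustration only)
id,coefficient,centralized
whole_grains,0.8,0.6097560975609757
wholegrain_bread,0.8,0.6097560975609757
barley,0.8,0.6097560975609757
bulgur,0.8,0.6097560975609757
refined_grains,-0.7,-0.6463414634146342
white_bread,-0.7,-0.6463414634146342
white_rice,-0.7,-0.6463414634146342
pasta,-0.7,-0.6463414634146342
legumes,0.6,0.3170731707317074
lentils,0.6,0.3170731707317074
beans,0.6,0.3170731707317074
nuts_seeds,0.5,-0.012195121951219523
nuts,0.5,-0.012195121951219523
seeds,0.5,-0.012195121951219523
vegetable_oils,0.2,-0.19512195121951215
olive_oil,0.7,0.41463414634146334
butter,-0.5,-0.4390243902439024
hydrogenated_fats,-0.9,-0.926829268292683
soft_drinks,-0.8,-0.8170731707317074
coffee,0.1,-0.2682926829268293
tea,0.15,-0.2195121951219512
processed_foods,-0.85,-0.8780487804878049
fast_food,-0.85,-0.8780487804878049
salty_snacks,-0.85,-0.8780487804878049
sweets,-0.75,-0.7560975609756098
sugar,-0.75,-0.7560975609756098
confectionery,-0.75,-0.7560975609756098
salt,-0.45,-0.41463414634146345
fruits,0.9,0.7682926829268293
apples,0.9,0.7682926829268293
citrus,0.9,0.7682926829268293
berries,0.9,0.7682926829268293
dried_fruit,0.9,0.7682926829268293
other_fruit,0.9,0.7682926829268293
vegetables,0.95,0.9268292682926829
leafy_veg,0.95,0.9268292682926829
root_veg,0.95,0.9268292682926829
tomatoes,0.95,0.9268292682926829
cucurbits,0.95,0.9268292682926829
alliums,0.95,0.9268292682926829
other_veg,0.95,0.9268292682926829
red_meat,-0.6,-0.524390243902439
processed_meat,-0.95,-0.9634146341463414
white_meat,0.3,-0.13414634146341464
fish,0.65,0.3902439024390243
dairy_high_fat,-0.3,-0.3414634146341463
dairy_low_fat,0.35,-0.09756097560975607
eggs,0.05,-0.29268292682926833
diet_drinks,-0.4,-0.3780487804878049
alcoholic_drinks,-0.55,-0.47560975609756095
vitamins_minerals,0.55,0.15853658536585358
vitamin_c,0.55,0.15853658536585358
vitamin_e,0.55,0.15853658536585358
vitamin_a,0.55,0.15853658536585358
folate,0.55,0.15853658536585358
zinc,0.55,0.15853658536585358
selenium,0.55,0.15853658536585358
magnesium,0.55,0.15853658536585358
calcium,0.55,0.15853658536585358
iron,0.55,0.15853658536585358
phytochemicals,0.75,0.4878048780487805
polyphenols,0.75,0.4878048780487805
carotenoids,0.75,0.4878048780487805
phytosterols,0.75,0.4878048780487805
flavonoids,0.75,0.4878048780487805
fiber,0.85,0.6829268292682926
omega3,0.62,0.36585365853658547
dietary_supplements,0.25,-0.1707317073170732
whole grains,0.8,0.6097560975609757
refined grains,-0.7,-0.6463414634146342
nuts and seeds,0.5,-0.012195121951219523
oils,0.44999999999999996,-0.07317073170731703
refined fats,-0.7,-0.6463414634146342
soft drinks,-0.8,-0.8170731707317074
coffee/tea/waters,0.125,-0.24390243902439024
processed foods,-0.6833333333333335,-0.5609756097560976
red meat,-0.6,-0.524390243902439
processed meat,-0.95,-0.9634146341463414
white meat,0.3,-0.13414634146341464
dairy,0.03333333333333333,-0.31707317073170727
diet drinks,-0.4,-0.3780487804878049
alcoholic drinks,-0.55,-0.47560975609756095
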