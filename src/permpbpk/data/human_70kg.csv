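# Reference adult human physiology: 70 kg body weight, 300 L/h cardiac output,
# hematocrit 0.45, density 1 kg/L for all tissues and blood.
# V_total_L includes the tissue's residual blood. For the liver the flow column
# is the hepatic ARTERIAL blood flow; portal inflow (pancreas+spleen+gut) is
# added by the loader. Lung flow is the cardiac output. Blood-pool rows carry
# only a total volume (split 45/55 cells/plasma by the loader).
tissue,V_total_L,V_residual_blood_L,V_ew_L,V_iw_L,Q_blood_L_per_h
adipose,14.5,0.14499999999999999,1.9575,12.397500000000001,16.216216216216218
bone,10.5,0.43049999999999999,1.05,9.019499999999999,16.216216216216218
brain,1.45,0.053649999999999996,0.2349,1.1614499999999999,38.918918918918919
gut,1.1699999999999999,0.028079999999999997,0.32993999999999996,0.81197999999999992,48.648648648648653
heart,0.33000000000000002,0.020130000000000002,0.10560000000000001,0.20427000000000001,12.972972972972974
kidney,0.31,0.032549999999999996,0.084630000000000011,0.19281999999999996,61.621621621621628
liver,1.8,0.20700000000000002,0.2898,1.3031999999999999,21.081081081081081
lung,0.5,0.13125000000000001,0.16800000000000001,0.20075000000000001,300
muscle,32.267310061601663,0.8389500616016432,2.5491174948665312,28.879242505133487,55.135135135135144
pancreas,0.14000000000000001,0.0252,0.016800000000000002,0.098000000000000004,3.2432432432432434
skin,3.2999999999999998,0.062699999999999992,1.2605999999999999,1.9766999999999999,16.216216216216218
spleen,0.14999999999999999,0.042299999999999997,0.031049999999999998,0.076649999999999996,9.7297297297297298
arterial_blood,1.1108966461327856,1.1108966461327856,0,0,0
venous_blood,2.2217932922655712,2.2217932922655712,0,0,0
portal_vein,0.25,0.25,0,0,0
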