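# Reference per-class evaluation metrics of a 39-class species-phenostage
# classifier (linear SVM on 1792-d deep image features; 80/20 split).
# Columns: species binomial, phenostage label, training/test image counts,
# per-class F1, recall, precision as published (2 d.p.). version: 1
species,stage,train_n,test_n,f1,recall,precision
Acer platanoides,flowering,80,19,1,1,1
Acer platanoides,fruit,73,18,1,1,1
Acer platanoides,senescence,57,14,0.96,0.92,1
Acer platanoides,vegetative,84,20,0.97,1,0.95
Aesculus hippocastanum,flowering_bud,33,8,0.82,0.87,0.77
Aesculus hippocastanum,flowering,64,15,0.93,0.93,0.93
Aesculus hippocastanum,unripe_fruit,64,15,0.96,1,0.93
Aesculus hippocastanum,ripe_fruit,64,15,1,1,1
Aesculus hippocastanum,vegetative,64,15,0.92,0.86,1
Betula pendula,flowering,32,7,0.93,1,0.87
Betula pendula,fruit,16,4,1,1,1
Betula pendula,senescence,32,7,0.83,0.71,1
Betula pendula,vegetative,31,7,0.80,0.85,0.75
Cornus mas,flowering,65,16,1,1,1
Cornus mas,unripe_fruit,39,9,0.88,0.88,0.88
Cornus mas,ripe_fruit,77,19,0.97,0.94,1
Cornus mas,vegetative,44,10,0.90,1,0.83
Crataegus laevigata,flowering_bud,32,6,0.88,0.87,0.87
Crataegus laevigata,flowering,50,12,0.95,0.91,1
Crataegus laevigata,ripe_fruit,46,11,1,1,1
Crataegus laevigata,vegetative,52,13,0.92,0.92,0.92
Fagus sylvatica,seedling,19,4,1,1,1
Fagus sylvatica,flowering,19,4,1,1,1
Fagus sylvatica,fruit,79,19,1,1,1
Fagus sylvatica,senescence,90,22,0.95,0.95,0.95
Fagus sylvatica,vegetative,54,13,0.92,0.92,0.92
Rosa canina,flowering,106,26,1,1,1
Rosa canina,ripe_fruit,80,19,1,1,1
Rosa canina,vegetative,74,18,1,1,1
Sambucus nigra,flowering_bud,78,19,0.94,0.94,0.94
Sambucus nigra,flowering,86,21,1,1,1
Sambucus nigra,unripe_fruit,80,20,0.90,0.90,0.90
Sambucus nigra,ripe_fruit,97,24,0.95,0.95,0.95
Sambucus nigra,vegetative,68,16,1,1,1
Sorbus aucuparia,flowering_bud,32,7,0.93,1,0.87
Sorbus aucuparia,flowering,86,21,0.97,0.95,1
Sorbus aucuparia,ripe_fruit,84,20,0.95,1,0.90
Sorbus aucuparia,senescence,19,4,0.66,0.50,1
Sorbus aucuparia,vegetative,81,20,1,1,1
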