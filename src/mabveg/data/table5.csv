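predicted\reference,Quercus variabilis,Quercus aliena var. acuteserrata,Quercus liaotungensis,Pinus armandii,Birch forest,Mixed forest,Abies fargesii,Larix chinensis,Subalpine shrub and meadow,Cultivated plants,Non-vegetation
Quercus variabilis,166,23,5,1,0,0,0,0,0,2,0
Quercus aliena var. acuteserrata,11,146,2,0,1,6,0,0,0,1,0
Quercus liaotungensis,1,16,89,3,4,6,0,0,0,0,0
Pinus armandii,0,4,1,116,2,0,1,0,0,0,0
Birch forest,0,0,3,1,98,4,8,2,0,0,0
Mixed forest,0,6,1,1,0,84,0,1,0,0,0
Abies fargesii,0,0,0,0,3,1,81,0,0,0,0
Larix chinensis,0,0,0,0,0,0,1,55,3,0,0
Subalpine shrub and meadow,0,0,0,0,0,0,0,1,9,0,0
Cultivated plants,0,0,0,0,0,0,0,0,0,27,0
Non-vegetation,0,0,0,0,0,0,0,0,0,0,3
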