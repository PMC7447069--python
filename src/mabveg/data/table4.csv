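predicted\reference,Quercus variabilis,Quercus aliena var. acuteserrata,Quercus liaotungensis,Pinus armandii,Birch forest,Mixed forest,Abies fargesii,Larix chinensis,Subalpine shrub and meadow,Cultivated plants,Non-vegetation
Quercus variabilis,197,11,1,0,4,7,0,0,0,0,0
Quercus aliena var. acuteserrata,4,165,3,0,2,4,0,0,0,1,0
Quercus liaotungensis,0,7,87,1,1,4,0,0,0,0,0
Pinus armandii,0,0,0,64,0,2,0,0,0,0,0
Birch forest,0,2,0,0,86,7,1,0,0,0,0
Mixed forest,0,1,0,3,2,109,2,0,0,1,0
Abies fargesii,0,0,0,0,0,4,120,0,0,0,0
Larix chinensis,0,0,0,0,0,1,0,46,2,0,0
Subalpine shrub and meadow,0,0,0,0,0,0,0,0,18,0,0
Cultivated plants,0,0,0,0,0,0,0,0,0,26,0
Non-vegetation,0,0,0,0,0,0,0,0,0,0,4
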