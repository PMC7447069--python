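formation,SpectralClustering,GaussianMixture,AgglomerativeClustering,DBSCAN,MeanShift,KMeans
Quercus variabilis,0.81,0.85,0.79,0.83,0.77,0.82
Quercus aliena var. acuteserrata,0.86,0.93,0.89,0.84,0.76,0.86
Quercus liaotungensis,0.76,0.84,0.72,0.78,0.74,0.84
Pinus armandii,0.76,0.81,0.81,0.70,0.78,0.94
Birch forest,0.90,0.79,0.86,0.74,0.50,0.79
Mixed forest,0.79,0.87,0.71,0.77,0.73,0.84
Abies fargesii,0.86,0.89,0.88,0.67,0.79,0.96
Larix chinensis,0.83,0.78,0.82,0.68,0.81,0.88
Subalpine shrub and meadow,0.89,0.83,0.81,0.61,0.76,0.89
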