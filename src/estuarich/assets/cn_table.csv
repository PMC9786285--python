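lulc_group,soil_group,cn
developed,A,77
developed,B,85
developed,C,90
developed,D,92
cropland,A,67
cropland,B,78
cropland,C,85
cropland,D,89
forest,A,30
forest,B,55
forest,C,70
forest,D,77
palustrine_wetland,A,100
palustrine_wetland,B,100
palustrine_wetland,C,100
palustrine_wetland,D,100
estuarine_wetland,A,100
estuarine_wetland,B,100
estuarine_wetland,C,100
estuarine_wetland,D,100
barren,A,77
barren,B,86
barren,C,91
barren,D,94
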