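# Continental wetland extent by type, 2020 survey figures (km²).
# The combined mangrove/seasonal row closes the table to the published
# 947,750 km² total; the survey quotes those two types only as percentages.
zone,wetland_type,area_km2
Africa,marsh,436743
Africa,swamp,231776
Africa,peatland,208842
Africa,mangrove_and_seasonal,70389
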