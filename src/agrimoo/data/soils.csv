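name,clay_pct,silt_pct,sand_pct,soc_pct,ph,bulk_density,y_pot
Clay,76,14,10,2.49,7.63,1.23,8.7
Sandy Clay,36,15,49,1.83,7.14,1.38,7.0
Sandy Loam,14,18,68,0.96,6.03,1.33,7.5
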