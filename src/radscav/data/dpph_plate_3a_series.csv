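compound,concentration_ug_ml,od_sample,replicate
CONTROL,,0.800,1
CONTROL,,0.800,2
CONTROL,,0.800,3
3a,265,0.560,1
3a,265,0.560,2
3a,265,0.560,3
3a,128,0.608,1
3a,128,0.608,2
3a,128,0.608,3
3a,32,0.800,1
3a,32,0.800,2
3a,32,0.800,3
3a,8,0.800,1
3a,8,0.800,2
3a,8,0.800,3
3b,265,0.728,1
3b,128,0.744,1
3b,32,0.800,1
3b,8,0.800,1
3c,265,0.616,1
3c,128,0.640,1
3c,32,0.800,1
3c,8,0.800,1
3d,265,0.720,1
3d,128,0.728,1
3d,32,0.800,1
3d,8,0.800,1
3e,265,0.632,1
3e,128,0.656,1
3e,32,0.800,1
3e,8,0.800,1
Quercetin,265,0.000,1
Quercetin,128,0.000,1
Quercetin,32,0.436,1
Quercetin,8,0.800,1
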