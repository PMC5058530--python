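site_id,centroid_x,centroid_y,forest_cover
s1,0,0,19
s2,5000,0,28
s3,10000,0,34
s4,15000,0,43
s5,20000,0,50
s6,25000,0,59
s7,30000,0,63
s8,35000,0,70
s9,40000,0,83
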