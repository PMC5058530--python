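site_id,forest_cover,adults,seedlings,assigned_same_landscape,assigned_other_landscape,assigned_total
s1,19,52,27,3,0,3
s2,28,14,11,1,0,1
s3,34,13,5,1,0,1
s4,43,18,26,3,0,3
s5,50,27,51,3,2,5
s6,59,28,41,2,1,3
s7,63,51,70,3,1,4
s8,70,26,26,0,0,0
s9,83,17,14,0,1,1
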