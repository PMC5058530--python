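progeny_id,progeny_cover,parent_id,parent_cover,pp,distance_km
P172,63,A185,70,0.998672931,2
P061,50,A003,43,0.999930484,5
P275,83,A018,43,0.998812611,8
P106,59,A016,43,0.999767368,10
P055,50,A080,59,0.999223400,13
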