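species_id,T,D,M,Tr,LH,T+D,T+LH,D+LH,T+D+M,T+D+Tr,T+D+LH
s1,3,3,2,3,3,6,6,6,8,9,9
s2,0,0,0,0,0,0,0,0,0,0,0
s3,1,1,1,1,1,2,2,2,3,3,3
s4,2,2,2,2,3,4,5,5,6,6,7
s5,0,0,2,3,3,0,3,3,2,3,3
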