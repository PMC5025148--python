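cell_id,count_based,score_based,biodiversity
A1,True,False,True
A3,False,False,False
B1,True,True,True
B2,True,False,False
C1,True,False,True
C2,False,False,False
C3,True,False,False
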