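cell_id,n_records,has_data,richness_total,richness_threatened,richness_endemic,richness_sensitive,mean_T+D,mean_T+LH,mean_D+LH,mean_T+D+M,mean_T+D+Tr,mean_T+D+LH
A1,3,True,2,0,1,1,0.0,1.5,1.5,1.0,1.5,1.5
A2,0,False,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
A3,1,True,1,0,0,0,0.0,0.0,0.0,0.0,0.0,0.0
B1,3,True,2,2,2,2,5.0,5.5,5.5,7.0,7.5,8.0
B2,2,True,2,2,2,1,4.0,4.0,4.0,5.5,6.0,6.0
B3,0,False,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
C1,3,True,2,1,1,0,1.0,1.0,1.0,1.5,1.5,1.5
C2,1,True,1,0,0,0,0.0,0.0,0.0,0.0,0.0,0.0
C3,3,True,2,1,1,1,2.0,2.5,2.5,3.0,3.0,3.5
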