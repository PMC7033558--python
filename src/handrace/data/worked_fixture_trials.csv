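subject_id,group,block,image_id,stimulus_side,response,rt,noisy_recording
S1,controls,1,f01,left,right,1.00,False
S1,controls,1,f02,left,left,1.02,False
S1,controls,1,f03,left,left,1.04,False
S1,controls,1,f04,left,left,1.06,False
S1,controls,1,f05,left,left,1.08,False
S1,controls,1,f06,left,left,1.10,False
S1,controls,1,f07,right,left,0.80,False
S1,controls,1,f08,right,right,0.82,False
S1,controls,1,f09,right,right,0.84,False
S1,controls,1,f10,right,right,0.86,False
S1,controls,1,f11,right,right,0.88,False
S1,controls,1,f12,right,right,0.90,False
S2,controls,1,f01,left,none,,False
S2,controls,1,f02,left,none,,False
S2,controls,1,f03,left,none,,False
S2,controls,1,f04,left,none,,False
S2,controls,1,f05,left,left,1.00,True
S2,controls,1,f06,left,left,1.05,False
S2,controls,1,f07,right,right,0.95,False
S2,controls,1,f08,right,right,0.97,False
S2,controls,1,f09,right,right,0.99,False
S2,controls,1,f10,right,right,1.01,False
S2,controls,1,f11,right,right,1.03,False
S2,controls,1,f12,right,right,1.07,False
S3,congenital,1,f07,right,right,1.20,False
S3,congenital,1,f08,right,right,1.22,False
S3,congenital,1,f09,right,right,1.24,False
S3,congenital,1,f10,right,right,1.26,False
S3,congenital,1,f11,right,right,1.28,False
S3,congenital,1,f12,right,left,1.30,False
S3,congenital,1,f01,left,left,1.30,False
S3,congenital,1,f02,left,left,1.32,False
S3,congenital,1,f03,left,left,1.34,False
S3,congenital,1,f04,left,left,1.36,False
S3,congenital,1,f05,left,right,1.38,False
S3,congenital,1,f06,left,right,1.40,False
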