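spine_id,level,cancer,lesion_type,age,sex,height_cm,weight_kg,bmd_mgHA_cm3,strength_kN,stiffness_kN_mm
VA15-AL,T11,Prostate,S,71,M,188.0,68.0,250.01,8.52,19.75
MD15-L,L4,Lung,S,60,M,175.3,85.7,194.83,9.58,14.37
VA15-AL,T7,Prostate,S,71,M,188.0,68.0,146.66,4.31,12.6
VA15,L1,Breast,M,60,F,162.6,40.8,324.68,10.72,40.83
VA15-S,T11,Breast,S,60,F,162.5,40.8,318.3,11.12,36.84
AL15,L5,Breast,S,59,F,170.2,79.4,155.98,7.47,15.3
GA1,T11,Kidney,L,71,M,170.2,54.4,91.3,1.87,9.68
MD14,T9,Lung,L,49,M,177.8,68.0,124.89,3.42,11.82
PA15,T8,Breast,S,60,F,165.1,68.0,240.47,5.35,9.94
MD15-A,L1,Lung,S,60,M,182.9,81.6,186.05,5.83,14.86
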