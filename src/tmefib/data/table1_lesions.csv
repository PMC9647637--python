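patient_id,lesion_id,age,gender,body_site,superficial,nodular,infiltrative,ulceration,any_tls,primary_tls,tls_stage
P01,L01,43,F,trunk,1,0,0,1,0,0,none
P02,L02,73,F,trunk,0,1,0,1,0,0,none
P02,L03,73,F,trunk,0,1,0,1,1,0,aggregate
P03,L04,88,F,head and neck,0,1,0,0,0,0,none
P04,L05,64,F,head and neck,1,0,0,1,0,0,none
P05,L06,71,M,head and neck,0,1,0,0,1,1,primary
P06,L07,66,M,head and neck,1,1,0,1,1,1,primary
P07,L08,75,M,extremity,0,1,0,1,1,0,aggregate
P08,L09,66,M,extremity,1,0,0,1,0,0,none
P08,L10,66,M,trunk,1,1,0,1,0,0,none
P08,L11,66,M,head and neck,0,1,0,1,0,0,none
P08,L12,66,M,head and neck,0,1,0,1,0,0,none
P08,L13,66,M,head and neck,1,0,0,1,1,1,primary
P09,L14,83,F,head and neck,0,1,1,0,1,1,primary
P10,L15,59,M,trunk,0,1,0,0,1,0,aggregate
P10,L16,59,M,trunk,0,1,0,0,1,1,primary
P11,L17,81,M,head and neck,0,1,0,1,1,0,aggregate
P12,L18,74,F,trunk,0,1,0,0,1,1,primary
P12,L19,74,F,trunk,0,1,0,1,0,0,none
P13,L20,,unknown,head and neck,1,1,1,1,1,1,primary
P14,L21,72,M,head and neck,0,1,1,1,0,0,none
P15,L22,90,M,head and neck,0,1,0,1,1,0,aggregate
P16,L23,51,M,trunk,1,1,0,1,1,0,aggregate
P17,L24,64,M,extremity,1,1,0,1,1,1,primary
P18,L25,62,M,head and neck,0,1,0,1,1,1,primary
P18,L26,62,M,head and neck,0,1,1,1,1,1,primary
P19,L27,53,F,head and neck,0,1,0,0,1,0,aggregate
P20,L28,80,F,head and neck,0,0,1,1,0,0,none
P21,L29,68,M,trunk,0,1,0,0,1,1,primary
P22,L30,54,M,trunk,1,1,0,0,1,0,aggregate
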