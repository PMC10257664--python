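patient_id,hla_a,cancer_type,group,infusions,response,duration_months,evaluable
C001,0201;1102,melanoma,none,2,NA,,False
C018,0101;1101,intrahepatic cholangiocarcinoma,none,3,NA,,False
C003,1101;1102,melanoma,none,2,PD,,True
C004,1101;1102,melanoma,none,8,PR,15,True
C020,0201;3303,melanoma,none,15,PR,27,True
C005,0201;0203,melanoma,low,8,PR,8,True
C008,1101;0207,melanoma,low,3,PD,,True
C012,1101;3303,colorectal cancer,low,6,SD,4,True
C013,0206;1101,melanoma,high,6,SD,4.37,True
C015,0201;1101,melanoma,high,6,SD,4,True
C017,1101;1101,melanoma,high,2,PD,,True
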