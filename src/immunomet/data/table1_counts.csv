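characteristic,category,count
age_at_diagnosis,<=40,134
age_at_diagnosis,41-50,247
age_at_diagnosis,>50,320
chemotherapy_type,FAC,74
chemotherapy_type,FAC+paclitaxel,236
chemotherapy_type,FAC+docetaxel,61
chemotherapy_type,FEC,33
chemotherapy_type,FEC+paclitaxel,73
chemotherapy_type,paclitaxel,65
chemotherapy_type,docetaxel,39
chemotherapy_type,unspecified,120
chemotherapy_response,pCR_or_RCB_0_1,188
chemotherapy_response,no_pCR_or_RCB_2_3,492
chemotherapy_response,unspecified,21
er_status,positive,385
er_status,negative,300
er_status,unspecified,16
her2_status,positive,65
her2_status,negative,561
her2_status,unspecified,75
subtype,Basal,211
subtype,LumA,216
subtype,LumB,135
subtype,HER2-E,74
subtype,Claudin-low,47
subtype,Normal-like,16
subtype,unspecified,2
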