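condition,icd_version,prefix
amenorrhea,9,626.0
amenorrhea,10,N91
dyslipidemia,9,272
dyslipidemia,10,E78
hypertension,9,401
hypertension,9,402
hypertension,9,403
hypertension,9,404
hypertension,9,405
hypertension,10,I10
hypertension,10,I11
hypertension,10,I12
hypertension,10,I13
hypertension,10,I15
diabetes,9,250
diabetes,10,E10
diabetes,10,E11
diabetes,10,E12
diabetes,10,E13
diabetes,10,E14
obesity,9,278.0
obesity,10,E66
ischemic_heart_disease,9,410
ischemic_heart_disease,9,411
ischemic_heart_disease,9,412
ischemic_heart_disease,9,413
ischemic_heart_disease,9,414
ischemic_heart_disease,10,I20
ischemic_heart_disease,10,I21
ischemic_heart_disease,10,I22
ischemic_heart_disease,10,I24
ischemic_heart_disease,10,I25
other_heart_disease,9,420
other_heart_disease,9,423
other_heart_disease,9,425
other_heart_disease,9,427
other_heart_disease,9,428
other_heart_disease,10,I30
other_heart_disease,10,I42
other_heart_disease,10,I47
other_heart_disease,10,I48
other_heart_disease,10,I49
other_heart_disease,10,I50
cerebrovascular_disease,9,430
cerebrovascular_disease,9,431
cerebrovascular_disease,9,432
cerebrovascular_disease,9,433
cerebrovascular_disease,9,434
cerebrovascular_disease,9,435
cerebrovascular_disease,9,436
cerebrovascular_disease,9,437
cerebrovascular_disease,9,438
cerebrovascular_disease,10,I60
cerebrovascular_disease,10,I61
cerebrovascular_disease,10,I62
cerebrovascular_disease,10,I63
cerebrovascular_disease,10,I64
cerebrovascular_disease,10,I65
cerebrovascular_disease,10,I66
cerebrovascular_disease,10,I67
cerebrovascular_disease,10,I69
hyperglycemia,9,790.2
hyperglycemia,10,R73
secondary_parkinsonism_dystonia,9,332.1
secondary_parkinsonism_dystonia,9,333.7
secondary_parkinsonism_dystonia,10,G21
secondary_parkinsonism_dystonia,10,G24
galactorrhea,9,611.6
galactorrhea,10,N64.3
sexual_dysfunction,9,302.7
sexual_dysfunction,10,F52
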