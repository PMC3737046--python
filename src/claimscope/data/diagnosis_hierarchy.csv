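level,category,icd_version,prefix
1,psychotic_disorders,9,291.3
1,psychotic_disorders,9,293.0
1,psychotic_disorders,9,293.1
1,psychotic_disorders,9,293.81
1,psychotic_disorders,9,293.82
1,psychotic_disorders,9,293.83
1,psychotic_disorders,9,295
1,psychotic_disorders,9,297
1,psychotic_disorders,9,298
1,psychotic_disorders,10,F20
1,psychotic_disorders,10,F21
1,psychotic_disorders,10,F22
1,psychotic_disorders,10,F23
1,psychotic_disorders,10,F24
1,psychotic_disorders,10,F25
1,psychotic_disorders,10,F26
1,psychotic_disorders,10,F27
1,psychotic_disorders,10,F28
1,psychotic_disorders,10,F29
1,psychotic_disorders,10,F06
1,psychotic_disorders,10,F09
2,bipolar,9,296.0
2,bipolar,9,296.1
2,bipolar,9,296.4
2,bipolar,9,296.5
2,bipolar,9,296.6
2,bipolar,9,296.7
2,bipolar,9,296.8
2,bipolar,9,296.9
2,bipolar,10,F30
2,bipolar,10,F31
2,bipolar,10,F34.0
2,bipolar,10,F38.0
3,pdd_mental_retardation,9,299
3,pdd_mental_retardation,9,317
3,pdd_mental_retardation,9,318
3,pdd_mental_retardation,9,319
3,pdd_mental_retardation,10,F70
3,pdd_mental_retardation,10,F71
3,pdd_mental_retardation,10,F72
3,pdd_mental_retardation,10,F73
3,pdd_mental_retardation,10,F74
3,pdd_mental_retardation,10,F75
3,pdd_mental_retardation,10,F76
3,pdd_mental_retardation,10,F77
3,pdd_mental_retardation,10,F78
3,pdd_mental_retardation,10,F79
3,pdd_mental_retardation,10,F84
3,pdd_mental_retardation,10,F89
4,tics,9,307.2
4,tics,10,F95
5,other_disruptive_disorders,9,301
5,other_disruptive_disorders,9,312
5,other_disruptive_disorders,9,313
5,other_disruptive_disorders,10,F60
5,other_disruptive_disorders,10,F61
5,other_disruptive_disorders,10,F62
5,other_disruptive_disorders,10,F63
5,other_disruptive_disorders,10,F68
5,other_disruptive_disorders,10,F91
5,other_disruptive_disorders,10,F92
6,adhd,9,314
6,adhd,10,F90
6,adhd,10,F98.8
7,depression,9,296.2
7,depression,9,296.3
7,depression,9,300.4
7,depression,9,311
7,depression,10,F32
7,depression,10,F33
7,depression,10,F34.1
7,depression,10,F38.1
7,depression,10,F39
8,anxiety_adjustment_sleep,9,300
8,anxiety_adjustment_sleep,9,307.4
8,anxiety_adjustment_sleep,9,308
8,anxiety_adjustment_sleep,9,309
8,anxiety_adjustment_sleep,9,310
8,anxiety_adjustment_sleep,9,780.5
8,anxiety_adjustment_sleep,10,F40
8,anxiety_adjustment_sleep,10,F41
8,anxiety_adjustment_sleep,10,F42
8,anxiety_adjustment_sleep,10,F43
8,anxiety_adjustment_sleep,10,F44
8,anxiety_adjustment_sleep,10,F45
8,anxiety_adjustment_sleep,10,F46
8,anxiety_adjustment_sleep,10,F47
8,anxiety_adjustment_sleep,10,F48
8,anxiety_adjustment_sleep,10,F51
8,anxiety_adjustment_sleep,10,F93.1
8,anxiety_adjustment_sleep,10,F93.2
8,anxiety_adjustment_sleep,10,F93.3
8,anxiety_adjustment_sleep,10,F93.4
8,anxiety_adjustment_sleep,10,F93.5
8,anxiety_adjustment_sleep,10,F93.6
8,anxiety_adjustment_sleep,10,F93.7
8,anxiety_adjustment_sleep,10,F93.8
8,anxiety_adjustment_sleep,10,F93.9
8,anxiety_adjustment_sleep,10,F07
9,eating_disorders,9,307.1
9,eating_disorders,9,307.5
9,eating_disorders,9,307.51
9,eating_disorders,10,F50
10,other,9,302
10,other,9,303
10,other,9,304
10,other,9,305
10,other,9,315
10,other,10,F10
10,other,10,F11
10,other,10,F12
10,other,10,F13
10,other,10,F14
10,other,10,F15
10,other,10,F16
10,other,10,F17
10,other,10,F18
10,other,10,F19
10,other,10,F65
10,other,10,F66
10,other,10,F06
10,other,10,F07
10,other,10,F80
10,other,10,F81
10,other,10,F82
10,other,10,F83
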