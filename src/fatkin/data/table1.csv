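subject_id,condition,variable,A_pct,tau_s,r_squared
01,HF,IMVC,64,34,0.81
01,HF,VA,69,95,0.81
01,HF,QTW,71,31,0.94
01,LF,IMVC,47,42,0.98
01,LF,VA,68,107,0.94
01,LF,QTW,67,79,0.95
02,HF,IMVC,65,52,0.96
02,HF,VA,83,18,0.96
02,HF,QTW,76,76,0.92
02,LF,IMVC,53,75,0.96
02,LF,VA,88,161,0.96
02,LF,QTW,59,49,0.98
03,HF,IMVC,66,32,0.92
03,HF,VA,85,8,0.83
03,HF,QTW,77,56,0.90
03,LF,IMVC,45,65,0.98
03,LF,VA,79,106,0.76
03,LF,QTW,56,25,0.98
04,HF,IMVC,73,19,0.72
04,HF,VA,83,14,0.76
04,HF,QTW,63,75,0.89
04,LF,IMVC,56,19,0.98
04,LF,VA,81,131,0.61
04,LF,QTW,58,91,0.98
05,HF,IMVC,70,17,0.69
05,HF,VA,56,11,0.98
05,HF,QTW,84,75,0.96
05,LF,IMVC,32,117,0.88
05,LF,VA,67,110,0.99
05,LF,QTW,71,68,0.91
06,HF,IMVC,63,25,0.94
06,HF,VA,90,71,0.92
06,HF,QTW,74,48,0.96
06,LF,IMVC,63,23,0.98
06,LF,VA,80,42,0.92
06,LF,QTW,70,23,0.98
07,HF,IMVC,74,12,0.90
07,HF,VA,83,10,0.81
07,HF,QTW,75,66,0.97
07,LF,IMVC,55,37,0.88
07,LF,VA,57,133,0.90
07,LF,QTW,73,28,0.96
08,HF,IMVC,59,33,0.98
08,HF,VA,74,51,0.92
08,HF,QTW,77,59,0.94
08,LF,IMVC,51,24,0.94
08,LF,VA,60,41,0.79
08,LF,QTW,70,8,0.88
09,HF,IMVC,73,61,0.90
09,HF,VA,91,32,0.94
09,HF,QTW,73,51,0.90
09,LF,IMVC,76,45,0.92
09,LF,VA,82,33,0.83
09,LF,QTW,70,51,0.86
10,HF,IMVC,51,33,0.94
10,HF,VA,97,80,0.98
10,HF,QTW,55,16,0.90
10,LF,IMVC,41,90,0.96
10,LF,VA,59,136,0.63
10,LF,QTW,58,75,0.98
11,HF,IMVC,70,17,0.81
11,HF,VA,78,60,0.89
11,HF,QTW,77,30,0.99
11,LF,IMVC,65,62,0.90
11,LF,VA,81,62,0.96
11,LF,QTW,61,29,0.98
12,HF,IMVC,55,24,0.85
12,HF,VA,84,70,0.81
12,HF,QTW,73,17,0.96
12,LF,IMVC,46,29,0.98
12,LF,VA,61,27,0.83
12,LF,QTW,79,14,0.88
13,HF,IMVC,48,42,0.96
13,HF,VA,97,35,0.99
13,HF,QTW,50,42,0.98
13,LF,IMVC,56,27,0.96
13,LF,VA,97,86,0.88
13,LF,QTW,41,28,0.94
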