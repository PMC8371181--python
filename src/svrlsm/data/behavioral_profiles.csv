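participant_id,ppvt_percentile,digit_span,freq_p,ppe,length_p,deficit_type
ABS,61,5.5,0.002,Yes,0.084,OWM+OLTM
AEF,1,3.5,0.001,Yes,0.031,OWM+OLTM
AES,39,5.5,<0.001,Yes,0.633,OLTM
BWN,94,2.5,0.870,No,0.010,OWM
CIE,1,4.0,<0.001,No,0.895,OLTM
CSS,42,4.0,0.130,No,<0.001,OWM
DBY,99,4.5,0.576,Yes,0.071,OLTM
DHY,87,5.0,0.002,Yes,0.667,OLTM
DPT,92,9.0,0.159,Yes,0.711,OLTM
DSK,55,3.5,<0.001,Yes,0.019,OWM+OLTM
DSN,91,5.5,0.015,Yes,0.235,OLTM
DTE,91,5.0,0.154,No,<0.001,OWM
ESG,6,4.0,0.036,Yes,0.017,OWM+OLTM
FCE,23,5.0,<0.001,Yes,<0.001,OWM+OLTM
JGL,60,6.0,0.061,Yes,0.300,OLTM
JRE,94,5.0,0.709,No,<0.001,OWM
KMN,27,0.0,<0.001,Yes,0.058,OWM+OLTM
KST,10,3.0,<0.001,Yes,0.004,OWM+OLTM
LC,97,3.0,0.024,Yes,0.671,OLTM
LHD,55,8.0,0.100,Yes,0.165,OLTM
LHT,1,3.0,0.245,No,0.920,OLTM
LPO,73,4.5,0.693,No,0.021,OWM
LSS,7,5.0,<0.001,No,0.450,OLTM
MK,4,3.5,1.000,Yes,0.021,OLTM
MLB,47,3.5,0.096,Yes,0.319,OLTM
MSO,50,3.5,0.002,No,<0.001,OWM+OLTM
PP,77,3.5,0.009,Yes,0.356,OLTM
PQS,99,5.0,0.184,Yes,<0.001,OWM+OLTM
RFZ,79,4.5,0.325,Yes,<0.001,OLTM
RHH,87,4.5,0.317,Yes,0.438,OLTM
RHN,73,6.0,0.007,Yes,0.027,OLTM
RSB,97,4.0,0.406,No,0.002,OWM
SDA,73,3.5,0.008,Yes,0.468,OLTM
TCI,30,4.5,0.001,Yes,0.126,OLTM
TCK,50,3.5,<0.001,Yes,0.002,OWM+OLTM
VBR,58,5.0,<0.001,Yes,0.271,OLTM
WCR,84,4.0,<0.001,Yes,<0.001,OWM+OLTM
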