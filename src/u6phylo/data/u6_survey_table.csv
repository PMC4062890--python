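region,sample_size,pct_u6,U6a without 235,U6a 235,U6a189 without 239,U6a189 239,U6b,U6b1,U6d,U6c
BRA,1400,0.57,12.5,-,87.5,-,-,-,-,-
HIS,4652,0.62,11.4,5.7,5.7,2.9,-,65.7,2.9,5.7
HUS,1062,0.75,-,-,25.0,-,25.0,37.5,12.5,-
AUS,1938,0.62,14.3,-,78.6,7.1,-,-,-,-
CUS,1959,0.31,12.5,-,50.0,31.3,6.3,-,-,-
POR,1187,2.53,10.0,23.3,20.0,23.3,6.7,3.3,13.3,-
AZO,471,2.55,33.3,-,16.7,8.3,8.3,-,33.3,-
MAD,155,3.23,60.0,-,20.0,-,-,-,20.0,-
CAV,323,3.10,20.0,-,70.0,-,10.0,-,-,-
SPA,4110,1.12,23.9,6.5,28.3,8.7,10.9,8.7,10.9,2.2
CAN,1040,16.15,4.2,0.6,2.4,1.2,1.2,76.8,1.2,12.5
NWE,11409,0.11,16.7,-,33.3,16.7,16.7,-,-,16.7
MdC,3680,0.41,33.3,-,46.7,6.7,-,-,13.3,-
MdE,8401,0.19,25.0,-,62.5,-,12.5,-,-,-
SAM,284,8.10,56.5,-,30.4,8.7,4.3,-,-,-
MOR,1508,8.89,30.6,6.0,37.3,9.7,9.7,-,2.2,4.5
ALG,299,6.69,15.0,15.0,55.0,5.0,-,-,-,10.0
TUN,951,5.36,33.3,-,39.2,19.6,2.0,-,-,5.9
NEA,1081,1.57,23.5,-,35.3,23.5,17.6,-,-,-
EAF,534,2.62,-,-,100.0,-,-,-,-,-
ARP,3224,1.09,11.4,34.3,22.9,-,31.4,-,-,-
WAF,3471,1.47,15.7,-,64.7,-,15.7,-,3.9,-
CAF,2099,0.43,33.3,-,44.4,-,22.2,-,-,-
JEW,2860,0.52,26.7,-,73.3,-,-,-,-,-
GYP,944,0.74,-,-,-,42.9,57.1,-,-,-
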