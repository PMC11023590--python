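variable,description,mean,sd,max,min,median
LS,"A ladder in [0, 10]",5.41,2.78,8.02,2.38,5.20
HLEB,Years,62,31,77,32,64
LEB,Years,70,35,85,39,72
GDP,Per capita $ PPP,16990,17334,141635,435,9850
GINI,"An index in [0, 0.99]",38.52,19.72,64.80,23.20,37.81
BUDP,Percentage,0.05,0.13,0.87,0.00,
CHRP,Percentage,0.50,0.39,0.99,0.00,
HINP,Percentage,0.02,0.07,0.74,0.00,
ISLP,Percentage,0.29,0.33,1.00,0.00,
JUDP,Percentage,0.01,0.05,0.74,0.00,
GEP,Percentage,102.34,51.19,150.79,20.88,102.47
GES,Percentage,77.53,44.62,163.93,5.93,84.56
GET,Percentage,35.60,27.98,148.53,0.20,29.92
EEP,Per student Thousand $ PPP,2.952,3.175,23.203,13,1.322
EES,Per student Thousand $ PPP,3.542,3.691,22.872,34,1.675
EET,Per student Thousand $ PPP,7.442,9.853,105.095,1,3.860
EE,Per capita $ PPP,791,840,5995,7,407
HE,Per capita $ PPP,1170,1297,10921,7,591
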