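variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,.0486883,.0235493,2.07,0.039,.0025324,.0948441
GINI,.0102602,.0018748,5.47,0.000,.0065856,.0139348
HLEB,.0855758,.0028453,30.08,0.000,.0799991,.0911525
BUDM,.0109795,.0656384,0.17,0.867,-.1176695,.1396284
CHRM,.3650706,.0424569,8.60,0.000,.2818566,.4482847
HINM,.104641,.1127042,0.93,0.353,-.1162552,.3255372
ISLM,.1954014,.0459599,4.25,0.000,.1053217,.2854812
JUDM,.9774281,.1563104,6.25,0.000,.6710653,1.283791
EEP,-.0039941,.011603,-0.34,0.731,-.0267356,.0187474
EES,.0631351,.0107401,5.88,0.000,.0420848,.0841854
EET,.0036957,.0014612,2.53,0.011,.0008319,.0065595
CONS,-1.207648,.1679655,-7.19,0.000,-1.536854,-.8784414
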