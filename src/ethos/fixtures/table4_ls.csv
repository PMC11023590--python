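variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,.0403637,.0236785,1.70,0.088,-.0060452,.0867726
GINI,.0114058,.0018951,6.02,0.000,.0076914,.0151202
HLEB,.0861713,.0028747,29.98,0.000,.080537,.0918056
BUDP,-.0994286,.1195767,-0.83,0.406,-.3337946,.1349373
CHRP,.3950921,.0842128,4.69,0.000,.2300381,.5601461
HINP,.6129055,.1476382,4.15,0.000,.3235399,.9022712
ISLP,.170761,.079773,2.14,0.032,.0144088,.3271131
JUDP,1.162371,.2194625,5.30,0.000,.7322327,1.59251
EEP,.004725,.0116454,0.41,0.685,-.0180996,.0275497
EES,.0603684,.0107534,5.61,0.000,.0392921,.0814448
EET,.0036683,.001471,2.49,0.013,.0007852,.0065515
CONS,-1.226336,.1770549,-6.93,0.000,-1.573357,-.8793146
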