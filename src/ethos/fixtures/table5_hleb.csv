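variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,1.285733,.1203556,10.68,0.000,1.049841,1.521626
GINI,-.101651,.0107568,-9.45,0.000,-.122734,-.080568
LSk4,3.013878,.1088944,27.68,0.000,2.800449,3.227307
BUDP,4.924426,.7025816,7.01,0.000,3.547391,6.30146
CHRP,-.1537398,.4980493,-0.31,0.758,-1.129898,.8224189
HINP,-.6936127,.8886547,-0.78,0.435,-2.435344,1.048119
ISLP,.9904331,.468389,2.11,0.034,.0724075,1.908459
JUDP,1.538791,1.292057,1.19,0.234,-.9935942,4.071177
GEP,.0590945,.0053441,11.06,0.000,.0486202,.0695687
GES,.0499777,.0049627,10.07,0.000,.0402511,.0597044
GET,.0539374,.0043893,12.29,0.000,.0453345,.0625404
CONS,25.28592,1.058082,23.90,0.000,23.21212,27.35972
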