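variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,.3064404,.0195803,15.65,0.000,.2680637,.3448171
GINI,.0043219,.0018201,2.37,0.018,.0007545,.0078893
HLEB,.0857813,.002916,29.42,0.000,.080066,.0914966
BUDM,-.0827249,.0657642,-1.26,0.208,-.2116203,.0461705
CHRM,.4139106,.0426604,9.70,0.000,.3302979,.4975234
HINM,.2180225,.1138638,1.91,0.056,-.0051466,.4411915
ISLM,.0561106,.0455312,1.23,0.218,-.033129,.1453502
JUDM,.923416,.1546504,5.97,0.000,.6203068,1.226525
GEP,-.0105601,.0008982,-11.76,0.000,-.0123206,-.0087996
GES,.0006183,.000851,0.73,0.467,-.0010496,.0022862
GET,-.0057967,.000735,-7.89,0.000,-.0072372,-.0043562
CONS,-1.841833,.1864447,-9.88,0.000,-2.207258,-1.476408
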