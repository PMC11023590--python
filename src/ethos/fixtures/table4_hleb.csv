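variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,4.041061,.1187563,34.03,0.000,3.808303,4.273819
GINI,-.1429581,.0112496,-12.71,0.000,-.1650068,-.1209093
LSk4,3.233527,.1117647,28.93,0.000,3.014472,3.452582
BUDP,2.4919,.7240369,3.44,0.001,1.072814,3.910987
CHRP,-.831695,.5134358,-1.62,0.105,-1.838011,.1746207
HINP,-2.228604,.898774,-2.48,0.013,-3.990169,-.4670398
ISLP,-.9146806,.4844517,-1.89,0.059,-1.864188,.0348272
JUDP,-.6081595,1.340684,-0.45,0.650,-3.235851,2.019532
EEP,.3682409,.0702906,5.24,0.000,.2304738,.506008
EES,-.4924509,.0649681,-7.58,0.000,-.6197861,-.3651157
EET,-.1230754,.0085803,-14.34,0.000,-.1398925,-.1062582
CONS,15.09239,1.042495,14.48,0.000,13.04913,17.13564
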