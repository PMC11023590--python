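variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,.3049576,.0196773,15.50,0.000,.2663908,.3435244
GINI,.0050731,.001847,2.75,0.006,.001453,.0086932
HLEB,.0857408,.0029633,28.93,0.000,.0799328,.0915488
BUDP,-.3962829,.1198036,-3.31,0.001,-.6310935,-.1614722
CHRP,.2834228,.0840418,3.37,0.001,.1187039,.4481417
HINP,.3395104,.150144,2.26,0.024,.0452336,.6337871
ISLP,-.1599931,.0792683,-2.02,0.044,-.315356,-.0046302
JUDP,1.003312,.2175787,4.61,0.000,.5768658,1.429759
GEP,-.0109379,.0008999,-12.15,0.000,-.0127017,-.009174
GES,.000837,.0008558,0.98,0.328,-.0008403,.0025143
GET,-.0058005,.000757,-7.66,0.000,-.0072841,-.0043169
CONS,-1.673609,.1956538,-8.55,0.000,-2.057084,-1.290135
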