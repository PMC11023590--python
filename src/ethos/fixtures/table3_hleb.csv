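variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,1.228951,.1218617,10.08,0.000,.9901068,1.467796
GINI,-.0958014,.0107498,-8.91,0.000,-.1168707,-.0747322
LSk4,3.113357,.1105013,28.17,0.000,2.896779,3.329936
BUDM,1.370708,.3929138,3.49,0.000,.6006113,2.140805
CHRM,-1.609453,.2585379,-6.23,0.000,-2.116178,-1.102728
HINM,-.1081894,.6824546,-0.16,0.874,-1.445776,1.229397
ISLM,-.5516751,.2725288,-2.02,0.043,-1.085822,-.0175284
JUDM,-.5346414,.9333037,-0.57,0.567,-2.363883,1.2946
GEP,.0583418,.0054009,10.80,0.000,.0477563,.0689273
GES,.0507417,.0049956,10.16,0.000,.0409505,.0605328
GET,.0537461,.0043178,12.45,0.000,.0452834,.0622087
CONS,26.47924,1.005573,26.33,0.000,24.50835,28.45013
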