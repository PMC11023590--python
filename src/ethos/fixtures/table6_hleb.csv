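variable,estimate,std_err,z,p_value,ci_low,ci_high
LNGDP,4.037765,.1196367,33.75,0.000,3.803281,4.272248
GINI,-.1360881,.0112475,-12.10,0.000,-.1581328,-.1140434
LSk4,3.283188,.11314,29.02,0.000,3.061438,3.504938
BUDM,.5345573,.4019733,1.33,0.184,-.2532959,1.322411
CHRM,-1.076862,.2635809,-4.09,0.000,-1.593472,-.5602532
HINM,.8294179,.6905268,1.20,0.230,-.5239898,2.182826
ISLM,-1.075826,.2820378,-3.81,0.000,-1.62861,-.5230424
JUDM,-1.766156,.9655384,-1.83,0.067,-3.658577,.1262642
EEP,.4170994,.0705822,5.91,0.000,.2787608,.5554381
EES,-.521436,.0654612,-7.97,0.000,-.6497377,-.3931343
EET,-.1257145,.0085895,-14.64,0.000,-.1425497,-.1088793
CONS,14.81959,.9967973,14.87,0.000,12.86591,16.77328
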