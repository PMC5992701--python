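state,no_components,iso_hypertension,iso_obesity,iso_hyperglycemia,iso_dyslipidemia,two_components,mets
no_components,0.837800,0.033900,0.038500,0.016400,0.048500,0.019800,0.005100
iso_hypertension,0.136900,0.614300,0.010600,0.021200,0.015900,0.174600,0.026500
iso_obesity,0.135000,0.000000,0.622600,0.000000,0.019300,0.187300,0.035800
iso_hyperglycemia,0.209300,0.034900,0.011600,0.511600,0.023300,0.174400,0.034900
iso_dyslipidemia,0.409600,0.016000,0.037200,0.021300,0.372300,0.133000,0.010600
two_components,0.086500,0.119000,0.140500,0.037800,0.048600,0.454100,0.113500
mets,0.020700,0.020700,0.041400,0.013800,0.000000,0.179300,0.724100
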