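state,no_components,iso_hypertension,iso_obesity,iso_hyperglycemia,iso_dyslipidemia,two_components,mets
no_components,0.764000,0.028600,0.067200,0.012900,0.073000,0.047200,0.007100
iso_hypertension,0.169500,0.491600,0.084800,0.016900,0.016900,0.169500,0.050800
iso_obesity,0.092500,0.002500,0.552500,0.005000,0.010000,0.287500,0.050000
iso_hyperglycemia,0.224100,0.069000,0.034500,0.431000,0.069000,0.069000,0.103400
iso_dyslipidemia,0.212800,0.025800,0.051600,0.012900,0.419400,0.206500,0.071000
two_components,0.059800,0.020000,0.215600,0.008000,0.043900,0.509000,0.143700
mets,0.018100,0.045500,0.100000,0.000000,0.018200,0.290900,0.527300
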