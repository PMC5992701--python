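state,no_components,iso_hypertension,iso_obesity,iso_hyperglycemia,iso_dyslipidemia,two_components,mets
no_components,0.676300,0.068100,0.057900,0.020400,0.112400,0.054600,0.010300
iso_hypertension,0.131100,0.489900,0.048400,0.024200,0.024200,0.217700,0.064500
iso_obesity,0.069400,0.008300,0.555700,0.008300,0.008300,0.277800,0.072200
iso_hyperglycemia,0.121600,0.013500,0.013500,0.527100,0.013500,0.189200,0.121600
iso_dyslipidemia,0.253700,0.034100,0.034200,0.014600,0.434100,0.156100,0.073200
two_components,0.028100,0.030700,0.130400,0.020500,0.042200,0.517900,0.230200
mets,0.020600,0.025700,0.023200,0.005200,0.000000,0.232000,0.693300
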