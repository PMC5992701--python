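state,no_components,iso_hypertension,iso_obesity,iso_hyperglycemia,iso_dyslipidemia,two_components,mets
no_components,0.870400,0.017000,0.038500,0.008100,0.037000,0.021500,0.007500
iso_hypertension,0.242600,0.529700,0.079200,0.000000,0.039600,0.089100,0.019800
iso_obesity,0.257800,0.013000,0.549500,0.002600,0.020800,0.122400,0.033900
iso_hyperglycemia,0.232800,0.017200,0.000000,0.577600,0.034500,0.120700,0.017200
iso_dyslipidemia,0.551100,0.048900,0.048900,0.013300,0.266700,0.066700,0.004400
two_components,0.246800,0.051100,0.208500,0.025500,0.038300,0.344700,0.085100
mets,0.142900,0.047600,0.047600,0.000000,0.047600,0.206300,0.508000
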