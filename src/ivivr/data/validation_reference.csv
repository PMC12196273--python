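# Head-to-head validation summary: observed and model-predicted metformin
# plasma concentrations (ng/mL) over the first 11 timepoints for the
# Glucophage IR 500 mg tablet (part of the training set) and the IR 850 mg
# tablet (independent validation set).
time_min,ir500_observed,ir500_predicted,ir850_observed,ir850_predicted
0,0,-24.66,0,-7.97
5,154.08,154.03,101.46,201.78
10,287.50,312.44,202.52,306.03
15,402.07,403.37,302.79,388.58
30,650.97,693.87,594.86,683.09
45,795.83,828.69,852.69,843.94
60,885.81,921.78,1012.76,965.14
90,1022.62,1052.07,1045.70,1085.21
120,1052.33,1079.44,1088.74,1091.99
150,1028.74,1029.44,1055.26,1026.70
180,913.82,960.40,1096.07,951.21
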