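# Observed and model-predicted metformin plasma concentrations (ng/mL) for
# the held-out tail timepoints of the extrapolation experiment, immediate-
# release (IR) and extended-release (XR) Glucophage formulations.
time_min,formulation,predicted,observed
1290,IR,73.41,77.93
1320,IR,76.02,76.98
1350,IR,78.18,75.95
1380,IR,76.25,74.78
1410,IR,75.42,73.41
1440,IR,79.09,71.80
1290,XR,65.32,68.24
1320,XR,65.91,65.08
1350,XR,64.53,62.11
1380,XR,60.86,59.34
1410,XR,57.34,56.75
1440,XR,59.27,54.34
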