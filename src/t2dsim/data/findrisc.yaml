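# Concise FINDRISC logistic model (Lindstrom & Tuomilehto 2003):
# 10-year risk of drug-treated diabetes from age band, BMI class, waist
# class, blood-pressure medication and history of high blood glucose.
# Standard errors drive the probabilistic sensitivity analysis; they are
# plausible defaults on the coefficient scale and fully configurable.
intercept:
  point: -5.514
  se: 0.180
age_band:
  "45to54": {point: 0.628, se: 0.130}
  "55to64": {point: 0.892, se: 0.135}
bmi_class:
  "25to30": {point: 0.165, se: 0.140}
  "gt30": {point: 0.936, se: 0.150}
waist_class:
  "mid": {point: 0.857, se: 0.145}
  "high": {point: 1.350, se: 0.150}
bp_medication:
  "yes": {point: 0.711, se: 0.130}
high_glucose_history:
  "yes": {point: 2.139, se: 0.160}
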