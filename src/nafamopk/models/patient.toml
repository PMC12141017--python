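# Final fitted parameter set: patient (central venous) sampling site.
# Clearances L/h, volumes L, concentrations ug/L, aPTT s, IIV as
# percent = 100*sqrt(omega^2), sigma_prop as a fraction.

name = "patient"
site = "patient"

[pk]
cl = 189.0
v1 = 7.01
q = 350.0
v2 = 55.0
fixed = ["q"]

[[pk.covariate]]
parameter = "v2"
covariate = "gas_flow_rate"
coefficient = -0.852
reference = 3.75

[pk.iiv]
cl = { percent = 61.3 }
v1 = { percent = 69.5, fixed = true }
q = { percent = 243.0, fixed = true }
v2 = { percent = 49.2, fixed = true }

[pk.error]
kind = "proportional"
sigma_prop = 0.287

[pd]
imax = 0.355
ic50 = 350.0
kin = 47.5
base = 34.5
fixed = ["ic50"]

[pd.iiv]
imax = { percent = 50.7, fixed = true }
ic50 = { percent = 70.6, fixed = true }
kin = { percent = 105.0 }
base = { percent = 20.7 }

[pd.error]
kind = "additive"
sigma_add = 2.83
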