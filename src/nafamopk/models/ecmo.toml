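# Final fitted parameter set: ECMO-circuit sampling site.
# The gas-flow covariate acts on CL here (on V2 in the patient model).
# omega for V2 and for IC50 are 0.000 (fixed): no IIV on those parameters.
# Whether omega_Kin (75.8%) was estimated or fixed is ambiguous in the
# source table (no RSE printed); it is treated as estimated here.

name = "ecmo"
site = "ecmo"

[pk]
cl = 85.2
v1 = 3.83
q = 46.7
v2 = 36.8
fixed = []

[[pk.covariate]]
parameter = "cl"
covariate = "gas_flow_rate"
coefficient = 0.0999
reference = 3.75

[pk.iiv]
cl = { percent = 29.5 }
v1 = { percent = 62.8, fixed = true }
q = { percent = 134.0, fixed = true }
v2 = { percent = 0.0, fixed = true }

[pk.error]
kind = "proportional"
sigma_prop = 0.309

[pd]
imax = 0.436
ic50 = 581.0
kin = 50.6
base = 33.0
fixed = ["ic50"]

[pd.iiv]
imax = { percent = 27.3, fixed = true }
ic50 = { percent = 0.0, fixed = true }
kin = { percent = 75.8 }
base = { percent = 21.2 }

[pd.error]
kind = "additive"
sigma_add = 3.43
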