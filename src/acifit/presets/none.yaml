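# No temperature scaling: every parameter is held at its reference value.
Kc:
  form: constant
  reference_value: 268.8
  units: "µmol mol⁻¹"
Ko:
  form: constant
  reference_value: 163.7
  units: "mmol mol⁻¹"
Gamma_star:
  form: constant
  reference_value: 36.94
  units: "µmol mol⁻¹"
Kp:
  form: constant
  reference_value: 80.0
  units: "µmol mol⁻¹"
gamma_star:
  form: constant
  reference_value: 0.000193
  units: "dimensionless"
Vcmax_norm:
  form: constant
  reference_value: 1.0
  units: "dimensionless"
Vpmax_norm:
  form: constant
  reference_value: 1.0
  units: "dimensionless"
J_norm:
  form: constant
  reference_value: 1.0
  units: "dimensionless"
Tp_norm:
  form: constant
  reference_value: 1.0
  units: "dimensionless"
RL_norm:
  form: constant
  reference_value: 1.0
  units: "dimensionless"
gmc_norm:
  form: constant
  reference_value: 1.0
  units: "dimensionless"
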