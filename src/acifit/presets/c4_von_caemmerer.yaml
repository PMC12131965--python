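# C4 temperature responses for the von Caemmerer model.  Reference
# values at 25 C; activation energies in kJ/mol.  Editable configuration
# data.
Kc:
  form: arrhenius
  reference_value: 650.0
  parameters: {activation_energy: 59.4}
  units: "µmol mol⁻¹"
Ko:
  form: arrhenius
  reference_value: 450.0
  parameters: {activation_energy: 36.0}
  units: "mmol mol⁻¹"
Kp:
  form: arrhenius
  reference_value: 80.0
  parameters: {activation_energy: 36.3}
  units: "µmol mol⁻¹"
gamma_star:
  form: arrhenius
  reference_value: 0.000193
  parameters: {activation_energy: 24.46}
  units: "dimensionless"
Vcmax_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 78.0}
  units: "dimensionless"
Vpmax_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 70.4}
  units: "dimensionless"
J_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 77.9}
  units: "dimensionless"
RL_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 66.4}
  units: "dimensionless"
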