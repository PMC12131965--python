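# C3 temperature responses (Arrhenius scaling of Rubisco kinetics and
# normalized rate multipliers).  Reference values are mole fractions at
# 25 C; activation energies in kJ/mol.  Editable configuration data.
Kc:
  form: arrhenius
  reference_value: 268.8
  parameters: {activation_energy: 80.99}
  units: "µmol mol⁻¹"
Ko:
  form: arrhenius
  reference_value: 163.7
  parameters: {activation_energy: 23.72}
  units: "mmol mol⁻¹"
Gamma_star:
  form: arrhenius
  reference_value: 36.94
  parameters: {activation_energy: 24.46}
  units: "µmol mol⁻¹"
Vcmax_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 65.33}
  units: "dimensionless"
J_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 43.9}
  units: "dimensionless"
Tp_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 53.1}
  units: "dimensionless"
RL_norm:
  form: arrhenius
  reference_value: 1.0
  parameters: {activation_energy: 46.39}
  units: "dimensionless"
gmc_norm:
  form: constant
  reference_value: 1.0
  units: "dimensionless"
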