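# Reference material constants for the cortical-bone viscoelastic /
# viscoplastic / damage model.  Moduli in GPa, eta01 in MPa*s, eta02 in
# kPa*s, strengths in MPa.  Strength-family and damage defaults are
# calibration starting points, not measured constants.
E00 = 2.9
E01 = 0.78
E02 = 4.18
eta01 = 0.24
eta02 = 0.40
nu = 0.3
S0 = 140.0
m = 18.24
sigma0_minus = 140.0
sigma0_plus = 86.8
tau0 = 49.0
chi0_minus = 0.5
chi0_plus = 0.5
alpha = 0.78
k_hard = 2.0
k_exp = 2.0
Emax = 10.0
zeta = 10.0
eta_D = 0.0
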