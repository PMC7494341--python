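omega_AT: 1.0
omega_RT: 1.0
omega_TT: 0.94
omega_AP: 1.0
omega_TP: 1.0
h_AT: 0.08
h_RT: 0.2
h_TT: 0.3
h_AP: 0.08
h_TP: 0.3
lambda_A: 0.86
lambda_R: 0.86
v_T: 50.0
v_P: 90.0
epsilon: 0.2
eta: 1.0
correlated_AR: false
A0: 1.0
R0: 1.0
T0: 0.0
P0: 0.9936406995230525
t_end: 6.0
dt: 0.001
hill_coefficient: 2
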