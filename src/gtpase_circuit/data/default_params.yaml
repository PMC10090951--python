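hill1_ec50: 0.06
hill1_n: 0.8505
hill2_ec50: 0.135
hill2_n: 45.0
hill3_ec50: 0.4459
hill3_n: 2.0877
hill4_ec50: 0.3
hill4_n: 2.0
hill5_ec50: 0.21
hill5_n: 1.0
hill6_ec50: 0.3079
hill6_n: 2.9142
hill7_ec50: 0.45
hill7_n: 3.8
hill8_ec50: 0.4
hill8_n: 1.0
hill9_ec50: 0.35
hill9_n: 1.85
tau_mGEF: 1.0
tau_mGAP: 12.0
tau_mGstar: 1.5
tau_tGEF: 4.0
tau_tGstar: 4.0
k_mGEF: 0.1
k_mGAP: 0.1168
k_mGstar: 0.0921
k_tGEF: 0.0
k_tGstar: 0.075
Y_mGEF_max: 0.5
Y_mGAP_max: 0.5
Y_tGEF_max: 1.0
tGAP: 0.3
beta_S: 0.003
k_S: 0.0005
alpha_S: 0.002
gamma: 0.008
K2: 1.0
lam: 0.06
mu: 0.004
K1: 0.3
K_capacity: 100.0
or_gate_c_tGEF: 0.24
or_gate_c_tGstar: 0.0017
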