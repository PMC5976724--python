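# HB + I_h reference parameter set
# units: ms, mV, mS/cm^2, uA/cm^2, uF/cm^2, deg C
C_m = 1.0
T = 36.0
g_d = 2.5
g_r = 2.8
g_sd = 0.21
g_sr = 0.28
g_l = 0.06
g_h = 0.4
V0_d = -25.0
V0_r = -25.0
V0_sd = -40.0
V0_h = -85.0
s_d = 0.25
s_r = 0.25
s_sd = 0.11
s_h = -0.14
tau_r = 2.0
tau_sd = 10.0
tau_sr = 35.0
tau_h = 125.0
eta = 0.014
kappa = 0.18
E_d = 50.0
E_r = -90.0
E_sd = 50.0
E_sr = -90.0
E_l = -80.0
E_h = -30.0
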