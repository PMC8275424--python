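# Rat-brain default parameter set.
# Units: lengths m, times s, rates s^-1, concentrations umol/L,
# association rates (umol L^-1 s)^-1, Dose umol, V_d L, SA_BBB m^2.

[dosing]
F = 1.0
Dose = 0.5
V_d = 0.2
K_a = 2e-4
K_e = 5e-5

[geometry]
r = 2.5e-6
l_cap = 5e-5

[transport]
D_star = 2.5e-16
v_ECF = 0.5e-6
v_blood = 1e-6

[bbb]
P = 0.1e-7
T_m_in = 0.1e-12
T_m_out = 0.1e-12
K_m_in = 1e2
K_m_out = 1e2
SA_BBB = 0.1e-7

[binding]
k1_on = 1e-1
k1_off = 1e-2
k2_on = 1e-2
k2_off = 1e-1
B1_tot = 5e-2
B2_tot = 5e1

[grid]
n_x = 23
n_y = 23
n_z = 23
n_edge = 23
dt = 0.01
t_end = 14.0
snapshot_times = 2.0, 8.0, 14.0
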