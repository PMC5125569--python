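# Default biophysical parameter set (SI units) and the morphology sweep used
# throughout the package. Starred single values are the defaults; the lists
# give the sweep values for cable length, cable diameter and soma diameter.
c: 1.0e-2          # specific membrane capacitance [F/m^2]
rho_m: 0.35714285714285715   # specific membrane conductance 1/2.8 [S/m^2]
rho_i: 0.6666666666666666    # specific internal conductance 1/1.5 [S/m]
D_s: 10.0e-6       # soma diameter [m]
D_d: 1.2e-6        # dendritic cable diameter [m]
L: 700.0e-6        # dendritic cable length [m]
sweep_L: [350.0e-6, 700.0e-6, 1050.0e-6]
sweep_D_d: [0.6e-6, 1.2e-6, 1.8e-6]
sweep_D_s: [5.0e-6, 10.0e-6, 15.0e-6]
V_T: 10.0e-3       # threshold voltage [V]
Delta_T: 1.5e-3    # threshold slope factor [V] (0 = LIF limit)
V_r: 0.0           # BS reset voltage [V]
V_r_prime: 5.0e-3  # point-model reset voltage [V]
V_s_lif: 10.0e-3   # spike voltage, LIF [V]
V_s_eif: 20.0e-3   # cutoff voltage, EIF [V]
T_ref: 1.5e-3      # refractory period [s]
V_0: 0.0           # linearization baseline [V]
tau: 0.5           # OU correlation time [ms]
delta: 3.0         # spike coincidence precision [ms]
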