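# SE-scenario kinetic parameters, ScHK2 hexokinase variant.
# Units: Michaelis/inhibition/equilibrium constants mol/m^2; kcat 1/s;
# vmax mol/(s*m) (fully loaded bead values); E_full mol/m.
K_mS: 0.9
K_mG: 0.12
K_mATP: 0.1
K_mF: 0.33
K_mF6P: 0.19
K_mG6P: 0.5
K_mG6PT: 0.7
K_mG6Pe: 0.7
K_mPi: 1.1
K_mPie: 1.1
K_iG6P: 0.9
K_iPi: 0.1
K_eq: 0.5
kcat_inv: 3379.60
kcat_hk: 1.06
kcat_pgi: 646.61
vmax_inv: 6.57e-5
vmax_hk: 2.03e-8
vmax_pgi_f: 12.57e-6
vmax_pgi_b: 12.57e-6
vmax_G6P_f: 3.23e-8
vmax_G6P_b: 3.23e-8
S: 50.0
ATP: 10.0
G6P_e: 1.0
Pi_e: 10.0
E_full: 1.94e-8
variant: ScHK2
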