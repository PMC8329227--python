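# peritonsim default parameter set, version 1
# Units: cm, mL, min, mmHg, mmol/mL.  Rate densities are per mL of tissue.
# Calibrated so that a typical dry-day APD prescription (six 90-min cycles,
# 2 L glucose 1.36%, 100 mL day fill) reproduces the reference cycle-by-cycle
# ultrafiltration pattern and the 18% -> ~36% near-surface hydration swing.
version: "1"
tissue_depth: 1.0
surface_area: 12500.0
theta_min: 0.17
theta_phys: 0.18
theta_max: 0.40
compliance_scale: 2.26
compliance_midpoint: 6.0
K0: 1.6e-6
K_sensitivity: 5.0
D0: 1.8e-4
D_sensitivity: 6.0
sigma_T: 0.0055
LpS_density: 2.5e-5
sigma_g: 0.185
PS_density: 0.04
P_blood: 15.0
Pi_blood_onc: 22.0
C_blood_glu: 0.005
three_pore: false
vaso_gain: 3.5
vaso_half_sat: 0.035
lymph_L0: 5.0e-5
lymph_P_sensitivity: 7.0e-5
lymph_P_onset: 0.6
lymph_P_sat: 4.0
ip_pressure_base: 0.95
ip_pressure_slope: 0.0045
residual_volume: 250.0
fill_rate: 200.0
drain_rate: 350.0
RT: 19343.0
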