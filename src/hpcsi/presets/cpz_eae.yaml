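# Calibrated study preset: four-arm neuroinflammation cohort
# (control / CPZ-EAE / CPZ-EAE + DMF / CPZ-EAE + FTY720).
#
# A single latent "inflammation burden" b drives all endpoints.  Group
# burden means are chosen so that exp(kpl_log_slope * delta_b) equals the
# designed lactate/pyruvate fold-changes: 2.1x disease vs control and
# 1.31x / 1.35x decreases under DMF / FTY720.  Marker group means encode
# the designed group contrasts directly (per-group intercepts on top of
# the shared-latent slope; the printed treatment responses are not
# monotone in any single latent ordering, so group means are free
# calibration constants).  Within-group slopes/noise are relative to the
# group mean: slope_g = within_slope * mean_g * direction,
# sd_g = within_noise * mean_g.
#
# Units: enzyme activities nmol/min/mg; immunofluorescence areas %;
# CD3 cells/mm^2; lesion volumes mm^3; kPL 1/s.

kpl_base: 0.029          # control-group geometric-mean kPL (1/s)
kpl_log_slope: 0.7419373 # ln(2.1): log-kPL increase per unit burden
burden_sd: 0.25
delivery_scale_sd: 0.15  # animal-to-animal polarization/transfer spread
csi_noise_sigma: 0.02    # k-space complex-noise SD per component
t1_noise_sigma: 0.02
t1_enhancement_fraction: 0.5
t1_k_sd: 4.0             # threshold multiplier used by the study analysis

groups:
  control:
    n_animals: 14
    burden_mean: 0.0
  cpz_eae:
    n_animals: 12
    burden_mean: 1.0
  cpz_eae_dmf:
    n_animals: 11
    burden_mean: 0.6361     # 1 - ln(1.31)/ln(2.1)
  cpz_eae_fty720:
    n_animals: 14
    burden_mean: 0.5955     # 1 - ln(1.35)/ln(2.1)

eae:
  cutpoints: [0.0, 1.2, 2.4, 3.6, 4.8, 6.0]
  slope: 1.5
  # target mean clinical scores; null groups use an all-zero category law
  target_means:
    control: zero
    cpz_eae: 2.6
    cpz_eae_dmf: 1.1
    cpz_eae_fty720: zero

lesion:
  # designed mean enhancing volumes (mm^3); FTY720 shows no enhancement
  means: {control: 0.30, cpz_eae: 1.56, cpz_eae_dmf: 0.90, cpz_eae_fty720: 0.30}
  within_slope: 0.5
  within_noise: 0.20

markers:
  within_slope: 0.3
  within_noise: 0.15
  table:
    # marker: [direction, control, cpz_eae, cpz_eae_dmf, cpz_eae_fty720]
    pdh:        [-1, 8.0,   0.9877, 3.6543, 3.1605]   # 8.1x down; 3.7x / 3.2x recovery
    ldh:        [ 0, 120.0, 120.0,  120.0,  120.0]    # unchanged
    iba1:       [ 1, 2.0,   14.0,   7.3684, 8.75]     # 7x up; -1.9x / -1.6x
    cd68:       [ 1, 0.4,   10.0,   4.0,    10.0]     # 25x up; -2.5x / unchanged
    cd3:        [ 1, 1.0,   455.0,  137.88, 23.096]   # 455x up; -3.3x / -19.7x
    pdk1:       [ 1, 0.15,  14.25,  5.70,   4.9138]   # 95x up; -2.5x / -2.9x
    gfap:       [ 1, 4.0,   14.0,   14.0,   14.0]     # 3.5x up; treatments no effect
    fibrinogen: [ 1, 0.5,   3.0,    2.5,    0.5]      # raised except FTY720
    myelin:     [-1, 70.0,  40.0,   45.0,   50.0]     # demyelination, partial rescue
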