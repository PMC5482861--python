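# Cohort presets for the four study groups (normal/FGR x arterial/venous).
#
# target_length_density_mm_per_cm3 is the group's published median vessel
# length density; density_sigma_ln = ln(q75/q25) / (2 * 0.67449) reproduces
# the published interquartile range under the log-normal within-group model.
# The tissue domain is scaled down to 8 cm^3 (length density is scale-free);
# trunk diameters approximate umbilical vessel calibres near the insertion.

normal_arterial:
  group: normal
  compartment: arterial
  trunk_diameter_um: 3000.0
  target_length_density_mm_per_cm3: 27.29   # IQR 19.65-42.44
  density_sigma_ln: 0.5708
  tissue_volume_cm3: 8.0
  n_generations: 24
  taper_ratio: 0.67
  taper_jitter_sd: 0.18
  segment_length_mm: 1.3
  segment_length_dispersion: 0.35
  bend_rate: 0.4
  bend_angle_deg: 45.0
  bend_angle_sd: 12.0
  branch_angle_deg: 70.0
  branch_angle_sd: 12.0
  terminal_diameter_um: 90.0
  breakage_prob: 0.3
  breakage_threshold_um: 100.0
  voxel_size_mm: 0.09
  noise_sd: 0.08
  rng_seed: 1

normal_venous:
  group: normal
  compartment: venous
  trunk_diameter_um: 4000.0
  target_length_density_mm_per_cm3: 13.39   # IQR 12.18-22.94
  density_sigma_ln: 0.4693
  tissue_volume_cm3: 8.0
  n_generations: 24
  taper_ratio: 0.67
  taper_jitter_sd: 0.18
  segment_length_mm: 1.3
  segment_length_dispersion: 0.35
  bend_rate: 0.4
  bend_angle_deg: 45.0
  bend_angle_sd: 12.0
  branch_angle_deg: 70.0
  branch_angle_sd: 12.0
  terminal_diameter_um: 90.0
  breakage_prob: 0.3
  breakage_threshold_um: 100.0
  voxel_size_mm: 0.09
  noise_sd: 0.08
  rng_seed: 2

fgr_arterial:
  group: fgr
  compartment: arterial
  trunk_diameter_um: 3000.0
  target_length_density_mm_per_cm3: 14.82   # IQR 13.13-18.10
  density_sigma_ln: 0.2380
  tissue_volume_cm3: 8.0
  n_generations: 24
  taper_ratio: 0.67
  taper_jitter_sd: 0.18
  segment_length_mm: 1.3
  segment_length_dispersion: 0.35
  bend_rate: 0.4
  bend_angle_deg: 45.0
  bend_angle_sd: 12.0
  branch_angle_deg: 70.0
  branch_angle_sd: 12.0
  terminal_diameter_um: 90.0
  breakage_prob: 0.3
  breakage_threshold_um: 100.0
  voxel_size_mm: 0.09
  noise_sd: 0.08
  rng_seed: 3

fgr_venous:
  group: fgr
  compartment: venous
  trunk_diameter_um: 4000.0
  target_length_density_mm_per_cm3: 32.10   # IQR 22.08-50.92
  density_sigma_ln: 0.6194
  tissue_volume_cm3: 8.0
  n_generations: 24
  taper_ratio: 0.67
  taper_jitter_sd: 0.18
  segment_length_mm: 1.3
  segment_length_dispersion: 0.35
  bend_rate: 0.4
  bend_angle_deg: 45.0
  bend_angle_sd: 12.0
  branch_angle_deg: 70.0
  branch_angle_sd: 12.0
  terminal_diameter_um: 90.0
  breakage_prob: 0.3
  breakage_threshold_um: 100.0
  voxel_size_mm: 0.09
  noise_sd: 0.08
  rng_seed: 4
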