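# Demo pipeline configuration: one trabecular and one cortical phantom
# imaged at both scanner resolutions, plus a 36-subject measurement-level
# paired cohort calibrated with 1000 bootstrap draws of 12 from 24.
seed: 20260925
output_dir: demo_output
site: tibia
n_subjects: 36
n_test: 12
n_boot: 1000
draw_size: 12
phantom_enabled: true
truth_voxel_um: 20.0
trab_phantom:
  extent_mm: [2.5, 2.5, 2.5]
  thickness_um: 150.0
  spacing_um: 500.0
cort_phantom:
  extent_mm: [2.0, 3.0, 3.0]
  shell_thickness_um: 1000.0
  pore_diameters_um: [70.0, 120.0]
  target_porosity: 0.06
tissue_density_mgHA: 1200.0
profiles:
  xcti: {voxel_um: 82.0, psf_sigma_um: 49.2, noise_sd_mgHA: 30.0}
  xctii: {voxel_um: 61.0, psf_sigma_um: 36.6, noise_sd_mgHA: 20.0}
gaussian_seg: {}
lh_seg: {}
xcti_indirect: true
figures: false
save_volumes: false
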