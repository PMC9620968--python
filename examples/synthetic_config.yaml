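# Shipped synthetic end-to-end run: every stage generates its planted
# synthetic system, analyses it, and records a recovered-vs-planted check
# in the manifest. Run with:
#   gpianchor analyze all --config examples/synthetic_config.yaml --out out
seed: 1
output_dir: gpianchor_out
temperature_K: 303.0
stages: [tilt, torsions, solvation, depth, contacts, cluster]
cutoffs:
  hydration_nm: 0.3
  contact_nm: 0.5
  cluster_rmsd_nm: 0.3
  hbond_distance_nm: 0.35
  hbond_angle_deg: 30.0
cluster:
  min_members: 40
  subsample: 5000
fes_bin_width_deg: 5.0
tilt_bin_width_deg: 2.5
plots: false
synthetic:
  bilayer: {nx: 8, ny: 8, midplane_z: 3.25}
  tilt: {mean_deg: 80.0, sd_deg: 10.0, ar1_rho: 0.5, n_frames: 2000}
  torsions:
    centers_deg: [300.0, 60.0, 180.0]   # gg / gt / tg basin centres
    weights: [0.70, 0.25, 0.05]
    kappa: 20.0
    n_frames: 20000
  solvation:
    hydration_targets: {2: 3, 3: 4, 4: 5, 5: 2, 6: 6}
    total_waters: 60
    hbond_lambda: 1.5
    hbond_frames: 500
  depth: {mean_depth_nm: 0.3, sd_depth_nm: 0.1, n_frames: 500}
  cluster: {k: 3, counts: [60, 50, 40], sigma_nm: 0.02}
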