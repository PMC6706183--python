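# Full pipeline on a simulated cohort.  Replace the simulate block with
#   gps_path / acc_path / meta_path to run on real Movebank-style CSVs.
simulate:
  n_individuals: 40
  seed: 7
  # thinned sampling keeps the demo quick; tag-default densities are
  # gps_interval_s [1, 1200] and acc_gap_min [0.5, 10]
  gps_interval_s: [600, 1200]
  acc_gap_min: [60, 120]
use_enet: true
alpha: 0.5
cv_folds: 5
seed: 7
out_dir: lifeline_out
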