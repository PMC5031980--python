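candidate_models:
  full:
  - sst
  - log_eke
  - ssha
  - sst_sd
  - ssha_sd
  - bathy
  reduced:
  - sst
  - ssha
  - log_eke
  spawning:
  - sst
  - ssha
  - log_chl
  - uy10
  - bathy
  - bathy_sd
  - moon
cutoff_max_fpr: 0.05
cv_k: 3
entry_month_day: 04-01
entry_years:
- 2008
- 2009
- 2010
grid_resolution: 0.25
master_seed: 0
n_crw: 15
n_days: 50
n_fish: 6
n_runs: 5
output_dir: run_output
prediction_end: '2010-08-26'
prediction_start: '2010-04-01'
preference:
  sst:
  - 24.0
  - 1.5
preference_strength: 4.5
scale_radii_km:
- 50.0
- 100.0
- 200.0
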