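# Demo configuration for `prmquant run`.
# Simulates a 3-analyte withanolide panel plus the digoxin-d3 internal
# standard, acquires a 10-level calibration series (triplicate) and 4 samples
# at 3 dilutions in PRM and MRM modes, quantifies, calibrates with 1/x
# weighting, and compares the modes by Deming regression.
seed: 17
out_dir: results_demo
panel_size: 3
internal_standard: digoxin_d3
levels_ng_ml: [0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0, 10000.0]
calibration_replicates: 3
n_samples: 4
dilutions: [1.0, 0.5, 0.05]
sample_concentration_ng_ml: 500.0
noise_cv: 0.05
gradient_length: 8.0
desolvation_temperature: 400.0
mz_tol_ppm: 25.0
n_fragments: 3
weighting: "1/x"
accuracy_tol: 0.20
variance_ratio: 1.0
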