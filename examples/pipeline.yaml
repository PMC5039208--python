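# Full-pipeline configuration at the default (emulated-study) conditions.
# Run with:  triplenet run --config examples/pipeline.yaml --out out/ --seed 1
cohort:
  n_subjects_per_group: {HR: 17, LR: 12}
  volume_shape: [24, 24, 18]
  n_timepoints: 120
  tr_seconds: 2.5
  drift_slope: 0.02
  noise_sd: 0.5

network_specs:
  - name: CEN
    blobs: [{center: [6, 6, 9], radius: 4.0, amplitude: 1.0}]
  - name: DMN
    blobs: [{center: [17, 6, 9], radius: 4.0, amplitude: 1.0}]
    loading_scale_per_group: {HR: 1.5, LR: 1.0}
  - name: SN
    blobs: [{center: [11, 17, 9], radius: 4.0, amplitude: 1.0}]

model:
  nodes: [CEN, DMN, SN]
  edges: [[SN, CEN, 0.6], [SN, DMN, 0.5]]
  noise_sd: 1.0

preproc: {n_discard: 5, detrend: true, smooth_fwhm_mm: 8.0}
ica_order: mdl
one_sample_alpha: 0.001
two_sample_alpha: 0.05
bn_search: exhaustive
n_permutations: 1000
seed: 1
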