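# Demo pipeline configuration: synthetic 3-region cohort.
# Run with:  scalefree analyze examples/demo.yaml
source:
  synthetic:
    regions:
      frontal: {low: 1.0, high: 1.6}
      temporal: {low: 1.0, high: 2.0}
      hippocampus: {low: 1.0, high: 2.4}
    n_subjects_per_region: 4
    n_channels_per_subject: 2
    duration_s: 20.48
    seed: 0
bands:
  low:
    f_lo: 0.5
    f_hi: 4.0
    filter: {kind: lowpass, order: 7, cutoff_hz: 8.0, zero_phase: true}
  high:
    f_lo: 33.0
    f_hi: 80.0
    filter: {kind: highpass, order: 7, cutoff_hz: 33.0, zero_phase: true}
nperseg: 2048
overlap: 0.5
window: hamming
out_dir: results/demo_run
seed: 0
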