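# Case-control study config: a compact synthetic cohort with a planted
# log2 shift in CD45 for the case group.  Planted effects always apply to
# group b, so the case label (AA) is listed second in group_labels.
# Run:  mifquant run-all --config examples/study.yaml --out out/ --seed 1
cohort:
  n_group_a: 10          # controls (study scale: 51)
  n_group_b: 10          # cases    (study scale: 49)
  fovs_per_section: [4, 6]   # study scale: [40, 200]
  shape: [160, 160]
  bit_depth: 12
  effect_log2:
    CD45: 0.8            # 1.6 section-score SDs at section_sigma_log2 = 0.5
  seed: 1
group_labels: [NAA, AA]
qc:
  artifact_fovs: []      # ids flagged during visual review
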