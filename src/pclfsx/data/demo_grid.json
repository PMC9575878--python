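{
  "description": "Synthetic 30-feature demonstration F1 grid (10 informative features): steep rise over the informative features, noisy plateau, global maximum at subset size 29.",
  "n_features": 30,
  "n_informative": 10,
  "T": 0.05,
  "g": [0.30, 0.42, 0.55, 0.66, 0.80, 0.87, 0.86, 0.88, 0.90, 0.93,
        0.920, 0.925, 0.918, 0.928, 0.922, 0.930, 0.921, 0.927, 0.919, 0.932,
        0.924, 0.929, 0.920, 0.931, 0.923, 0.926, 0.917, 0.933, 0.940, 0.925]
}
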