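feature_names=rmsd,r_asa
weights=-6.980062173883422,-2.871211670525348
intercept=6.765875184184868
threshold=0.5
meta.n_negatives=500
meta.n_positives=500
meta.seed=2024
meta.source=synthetic-feature-simulation-seed2024
meta.standardized=false
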