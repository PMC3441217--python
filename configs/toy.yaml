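# Bundled toy scenario: 3 developmental stages, paired technical replicates,
# 5,000 reads per replicate, default class mixture / isomiR rates / edit and
# SNP plans.  Used by the end-to-end demo and the determinism check.
rng_seed: 42
n_stages: 3
reads_per_replicate: 5000
mirna_count: 40
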