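# Demonstration pipeline configuration: a small synthetic cohort with
# planted differential expression (4 up, 4 down of 24 hairpins), one
# survival-associated locus, and planted 3'UTR target sites.
sim:
  seed: 42
  n_true_hairpins: 24
  n_decoy_loci: 24
  genome_length: 200000
  read_depth_per_locus: 50
  background_read_rate: 0.5
  n_pairs: 30
  nb_dispersion: 0.1
  planted_log2fc:
    hp001: 2.0
    hp002: 3.0
    hp003: 4.0
    hp004: 5.0
    hp009: -2.0
    hp010: -3.0
    hp011: -4.0
    hp012: -5.0
  default_log2fc: 0.0
  baseline_hazard: 0.000833
  hazard_ratio_high_vs_low: 3.0
  survival_loci: [hp004]
  censor_rate: 0.3
  n_utrs: 150
  planted_sites_per_mirna: 2
  target_hub_genes: 8
  n_background_features: 300
discover_seed: 101
scramble_seed: 23
n_shuffles: 99
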