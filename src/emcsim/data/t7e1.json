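{
  "name": "T7E1",
  "enzyme": {
    "p_cut_snv": 0.05,
    "p_cut_bulge": {"1": 0.6, "2-19": 0.7, "20+": 0.74},
    "cut_side": "3prime",
    "exo_nibbling_rate": 0.0,
    "background_small_fragment_mass": 0.0
  },
  "noise": {
    "baseline_fu": 2.0,
    "baseline_jitter_fu": 0.3,
    "exo_background_mass": 0.0,
    "exo_background_decay_nt": 8.0
  },
  "provenance": "Calibration fixture for the T7 endonuclease I model. The 20+ nt bulge cleavage probability (0.74) reproduces the reported plateau of the 50:50 titration (74% of heteroduplexes cleaved; an alternative calibration of ~0.80 matches the 'about 80% of heteroduplexes' reading). The resolvase's preference for indel bulges over single-base mismatches motivates the low but nonzero SNV probability; it is config, not a constant. No exonuclease nibbling; flat low baseline."
}
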