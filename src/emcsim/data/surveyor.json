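{
  "name": "Surveyor",
  "enzyme": {
    "p_cut_snv": 0.5,
    "p_cut_bulge": {"1": 0.35, "2-19": 0.5, "20+": 0.6},
    "cut_side": "3prime",
    "exo_nibbling_rate": 3.0,
    "background_small_fragment_mass": 0.15
  },
  "noise": {
    "baseline_fu": 6.0,
    "baseline_jitter_fu": 1.0,
    "exo_background_mass": 0.15,
    "exo_background_decay_nt": 8.0
  },
  "provenance": "Calibration fixture for the Surveyor (CELII) model. The 20+ nt bulge probability (0.6) reproduces the reported plateau of the 50:50 titration (60% of heteroduplexes cleaved). The single-strand nuclease's preference for single-base mismatches motivates p_cut_snv > T7E1's. Intrinsic 5' exonuclease activity: mean 3 nt nibbled per 5' end and 15% of fragment mass routed to a sub-25-bp degradation spectrum; elevated irregular baseline. Noise values are calibrated so the packaged exon-3 titration reproduces the reported 10% detection limit."
}
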