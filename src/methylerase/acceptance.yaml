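# Tolerance bands for the self-check report (methylerase.pipeline.reproduce).
# Bands, not code, so they can be audited and adjusted without touching logic.
targets:
  dilution_fold:
    low: 1.999999999
    high: 2.000000001
  residual_ratio_percent:
    low: 72.0
    high: 78.0
  replication_contribution_percent:
    low: 25.0
    high: 40.0
  arrest_center_log2:
    low: 0.45
    high: 0.55
  arrest_excess_percent:
    low: 40.0
    high: 50.0
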