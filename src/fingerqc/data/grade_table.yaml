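# Default 8-band quality classification for the (S_m, P_m, alpha) triple.
# Grade 1 is best, grade 8 worst; grade 8 is the implicit catch-all band.
# A value exactly on a threshold resolves to the better grade.
bands:
  - {grade: 1, min_sm: 0.95, pm_low: 95.0, pm_high: 105.0, max_alpha: 0.05}
  - {grade: 2, min_sm: 0.90, pm_low: 90.0, pm_high: 110.0, max_alpha: 0.10}
  - {grade: 3, min_sm: 0.85, pm_low: 80.0, pm_high: 120.0, max_alpha: 0.15}
  - {grade: 4, min_sm: 0.80, pm_low: 75.0, pm_high: 125.0, max_alpha: 0.20}
  - {grade: 5, min_sm: 0.70, pm_low: 70.0, pm_high: 130.0, max_alpha: 0.25}
  - {grade: 6, min_sm: 0.60, pm_low: 60.0, pm_high: 140.0, max_alpha: 0.30}
  - {grade: 7, min_sm: 0.50, pm_low: 50.0, pm_high: 150.0, max_alpha: 0.35}
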