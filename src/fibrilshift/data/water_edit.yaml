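# Per-site water-edit enhancement factors (dimensionless, relative to the
# unedited experiment). These are free parameters ordered to reproduce the
# qualitative hydration contrasts of the water-edited experiments; they are
# NOT measured values.
site_factors:
  a: 1.0
  c: 1.0
  b: 1.5
  f: 1.8
  g: 1.9
  j: 1.8
# Carbon-resolved overrides: site b's hydroxymethyl C6 points into the
# fibril (tg conformer), so its enhancement is weaker than at C1/C4.
carbon_overrides:
  b:
    1: 1.8
    4: 1.8
    6: 1.3
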