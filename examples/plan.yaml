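# Single-replenishment planning input for `iondose plan`.
# Units: concentrations mg/L, volumes L.
target:
  Ca: 80
  K: 117
  NO3: 434
  volume: 15
state:
  ise: {Ca: 62.0, K: 88.5, NO3: 352.0}
  volume: 10.2
water: {}          # ion content of make-up water, mg/L
mg_p_mode: ratio   # peg Mg to Ca and H2PO4 to NO3 by uptake ratios
concentrate_multiple: 200
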