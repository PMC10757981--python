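# Five-step replenishment benchmark: target concentrations (mg/L) for the
# three electrode-measured ions and the target tank volume (L) per step,
# with the initial tank composition. Closed-loop lower limits: 20% on
# concentrations, 10% on volume. Units: mg/L and L.
initial:
  volume: 10
  concentrations: {Ca: 80, NO3: 434, K: 117}
steps:
  - {Ca: 80, NO3: 347.2, K: 93.6, volume: 15}
  - {Ca: 96, NO3: 347.2, K: 117, volume: 20}
  - {Ca: 64, NO3: 434, K: 140.4, volume: 25}
  - {Ca: 80, NO3: 434, K: 93.6, volume: 30}
  - {Ca: 96, NO3: 520.8, K: 140.4, volume: 40}
concentration_limit: 20
volume_limit: 10
concentrate_multiple: 200
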