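# Bundled riboflavin-model variable catalog: four medium-component inputs
# and the riboflavin output, each with peak-anchored low/medium/high
# triangular terms (shoulders at the universe edges).
kind: variable_catalog
variables:
- name: casamino
  role: input
  universe: [5.0, 20.0]
  terms:
  - {label: low, mf: [5.0, 5.0, 12.5]}
  - {label: medium, mf: [5.0, 12.5, 20.0]}
  - {label: high, mf: [12.5, 20.0, 20.0]}
- name: gtp
  role: input
  universe: [0.01, 0.04]
  terms:
  - {label: low, mf: [0.01, 0.01, 0.025]}
  - {label: medium, mf: [0.01, 0.025, 0.04]}
  - {label: high, mf: [0.025, 0.04, 0.04]}
- name: sodium_acetate
  role: input
  universe: [5.0, 15.0]
  terms:
  - {label: low, mf: [5.0, 5.0, 10.0]}
  - {label: medium, mf: [5.0, 10.0, 15.0]}
  - {label: high, mf: [10.0, 15.0, 15.0]}
- name: glycine
  role: input
  universe: [5.0, 15.0]
  terms:
  - {label: low, mf: [5.0, 5.0, 10.0]}
  - {label: medium, mf: [5.0, 10.0, 15.0]}
  - {label: high, mf: [10.0, 15.0, 15.0]}
- name: riboflavin
  role: output
  universe: [340.0, 440.0]
  terms:
  - {label: low, mf: [340.0, 340.0, 390.0]}
  - {label: medium, mf: [340.0, 390.0, 440.0]}
  - {label: high, mf: [390.0, 440.0, 440.0]}
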