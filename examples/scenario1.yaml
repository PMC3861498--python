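# Single-binary-exposure case-base scenario: exposure prevalence 0.3,
# exposure OR 2.5, marginal disease prevalence 0.1, population 100,000,
# case-sampling probability 0.05, base-sampling probability 0.005.
name: scenario1
prevalence: 0.1
population_size: 100000
gamma: 0.05
tau: 0.005
replicates: 10000
covariates:
  - {name: x, kind: binary, prevalence: 0.3}
odds_ratios: {x: 2.5}
methods: [present, sato, miettinen]
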