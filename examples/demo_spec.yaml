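# Demo synthetic chromosome: one palindrome, one satellite array, two genes.
chrom:
  name: chrDemo
  length: 800000
  gc: 0.41
features:
  - kind: palindrome
    position: 100000
    arm_len: 10000
    spacer_len: 30000
    divergence: 0.01
  - kind: satellite
    position: 400000
    unit_len: 171
    copies: 1800
    label: alpha
  - kind: gene
    start: 105000
    end: 107000
    label: ampliconic
    name: demoAmpGene
  - kind: gene
    start: 700000
    end: 702000
    label: ancestral
    name: demoAncGene
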