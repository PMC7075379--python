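# Dose-response model parameters for the brain treatment group.
# D50/gamma/alpha_beta per organ from the published clinical compilation used
# for radiobiological plan scoring; seriality adopted from the
# relative-seriality literature (equal to the compilation's alpha column,
# which matches published s values organ by organ).
site: brain
entries:
  - organ: PTV
    tissue_class: tumor
    d50_gy: 55.0
    gamma: 2.5
    alpha: null
    alpha_beta_gy: 10.0
    seriality: null
    endpoint: Control
    provenance: clinical dose-response compilation (brain target)
  - organ: Brain
    tissue_class: normal
    d50_gy: 60.0
    gamma: 2.6
    alpha: 0.64
    alpha_beta_gy: 3.0
    seriality: 0.64
    endpoint: Necrosis, infarction
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Brainstem
    tissue_class: normal
    d50_gy: 65.1
    gamma: 2.4
    alpha: 1.0
    alpha_beta_gy: 3.0
    seriality: 1.0
    endpoint: Necrosis, infarction
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Chiasm/optic nerve
    tissue_class: normal
    d50_gy: 65.0
    gamma: 2.3
    alpha: 1.0
    alpha_beta_gy: 3.0
    seriality: 1.0
    endpoint: Blindness
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Spinal cord
    tissue_class: normal
    d50_gy: 57.0
    gamma: 6.7
    alpha: 1.0
    alpha_beta_gy: 3.0
    seriality: 1.0
    endpoint: Myelopathy
    provenance: clinical dose-response compilation; s from relative-seriality literature
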