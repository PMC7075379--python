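# Dose-response model parameters for the lung treatment group.
site: lung
entries:
  - organ: PTV
    tissue_class: tumor
    d50_gy: 49.2
    gamma: 1.0
    alpha: null
    alpha_beta_gy: 10.0
    seriality: null
    endpoint: Control
    provenance: clinical dose-response compilation (lung target)
  - organ: Esophagus
    tissue_class: normal
    d50_gy: 68.0
    gamma: 2.8
    alpha: 3.4
    alpha_beta_gy: 3.0
    seriality: 3.4
    endpoint: Clinical stricture/perforation
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Heart
    tissue_class: normal
    d50_gy: 70.7
    gamma: 0.96
    alpha: 1.0
    alpha_beta_gy: 3.0
    seriality: 1.0
    endpoint: Cardiac mortality
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Lung
    tissue_class: normal
    d50_gy: 30.1
    gamma: 0.97
    alpha: 0.01
    alpha_beta_gy: 3.0
    seriality: 0.01
    endpoint: Radiation pneumonitis
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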