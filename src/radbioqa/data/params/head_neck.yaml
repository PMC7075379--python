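# Dose-response model parameters for the head-and-neck treatment group.
# High-risk and low-risk targets are scored separately (PTV7000 / PTV5400).
site: head_neck
entries:
  - organ: PTV7000
    tissue_class: tumor
    d50_gy: 51.0
    gamma: 7.5
    alpha: null
    alpha_beta_gy: 10.0
    seriality: null
    endpoint: Control
    provenance: clinical dose-response compilation (high-risk target)
  - organ: PTV5400
    tissue_class: tumor
    d50_gy: 44.0
    gamma: 4.0
    alpha: null
    alpha_beta_gy: 10.0
    seriality: null
    endpoint: Control
    provenance: clinical dose-response compilation (low-risk target)
  - organ: Parotid gland
    tissue_class: normal
    d50_gy: 46.0
    gamma: 1.8
    alpha: 0.01
    alpha_beta_gy: 3.0
    seriality: 0.01
    endpoint: Xerostomia
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
  - organ: Mandible
    tissue_class: normal
    d50_gy: 70.3
    gamma: 3.8
    alpha: 1.0
    alpha_beta_gy: 3.0
    seriality: 1.0
    endpoint: Marked limitation of joint function
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Brachial plexus
    tissue_class: normal
    d50_gy: 75.1
    gamma: 2.8
    alpha: 8.4
    alpha_beta_gy: 3.0
    seriality: 8.4
    endpoint: Nerve damage
    provenance: clinical dose-response compilation; s from relative-seriality literature
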