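# Dose-response model parameters shared by the pelvis and prostate
# treatment groups.  PTV7920 is the prostate target row, PTV6000 the pelvis
# target row; the default structure mappings pick the right one per site.
site: pelvis_prostate
entries:
  - organ: PTV7920
    tissue_class: tumor
    d50_gy: 63.0
    gamma: 5.0
    alpha: null
    alpha_beta_gy: 3.0
    seriality: null
    endpoint: Control
    provenance: clinical dose-response compilation (prostate target)
  - organ: PTV6000
    tissue_class: tumor
    d50_gy: 55.0
    gamma: 3.0
    alpha: null
    alpha_beta_gy: 3.0
    seriality: null
    endpoint: Control
    provenance: clinical dose-response compilation (pelvis target)
  - organ: Bladder
    tissue_class: normal
    d50_gy: 80.0
    gamma: 3.0
    alpha: 0.3
    alpha_beta_gy: 3.0
    seriality: 0.3
    endpoint: Symptomatic contracture
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Rectum
    tissue_class: normal
    d50_gy: 80.0
    gamma: 2.2
    alpha: 0.7
    alpha_beta_gy: 3.0
    seriality: 0.7
    endpoint: Proctitis, necrosis, fistula, stenosis
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Sigmoid
    tissue_class: normal
    d50_gy: 80.0
    gamma: 2.2
    alpha: 0.7
    alpha_beta_gy: 3.0
    seriality: 0.7
    endpoint: Ulceration
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Bowel
    tissue_class: normal
    d50_gy: 60.0
    gamma: 2.1
    alpha: 0.14
    alpha_beta_gy: 3.0
    seriality: 0.14
    endpoint: Stenosis
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Penile bulb
    tissue_class: normal
    d50_gy: 70.0
    gamma: 2.5
    alpha: 0.7
    alpha_beta_gy: 3.0
    seriality: 0.7
    endpoint: Erectile Dysfunction
    provenance: clinical dose-response compilation; s from relative-seriality literature
  - organ: Femur head
    tissue_class: normal
    d50_gy: 65.0
    gamma: 2.7
    alpha: 1.0
    alpha_beta_gy: 3.0
    seriality: 1.0
    endpoint: Necrosis
    provenance: clinical dose-response compilation; s from relative-seriality literature
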