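# Tissue parameter presets.
# tumor_c1: RCR Category-1 rapidly proliferating tumor (head-and-neck, lung).
# OAR presets carry no repopulation term (K = 0) and a 2 h repair half-time.
tumor_c1:
  alpha_beta: 10.0
  K: 0.9
  T_delay: 28.0
  class: tumor

oar_generic:
  alpha_beta: 3.0
  K: 0.0
  repair_half_time: 2.0
  class: oar

spinal_cord:
  alpha_beta: 2.0
  K: 0.0
  repair_half_time: 2.0
  class: oar
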