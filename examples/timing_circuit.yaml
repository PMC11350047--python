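# Binary mixed droplet with a time-delay circuit on the minority linker:
# 90% plain linker cleaved by free triggers, 10% gated linker whose triggers
# are released by RNase H from miRNA hybrids.
species:
  enzyme: 2.5e-2            # U/µL
  circuits:
    plain:
      linker_total: 0.7425  # µM
      trigger_total: 0.0
      free_trigger_extra: 2.5
    delayed:
      linker_total: 0.0825
      trigger_total: 1.0
      c_tilde: 1.5          # inhibitor RNA / trigger ratio
params:
  k_cat: 2.0e-3             # µM/s per U/µL
  K_m: 0.5                  # µM
  k_h_rna: 0.5              # 1/(µM·s)
  competition_mode: independent
  displacement_mode: two-step
  circuits:
    plain:   {k_on: 0.05, k_d: 0.5}
    delayed: {k_on: 0.05, k_d: 0.5}
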