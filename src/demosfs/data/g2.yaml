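# Best five-ecotype divergence model across the Chichijima, Hahajima and
# Mukojima Islands ("g2"): two ancestral lineages (the S-like lineage S/Sm/SG
# and the ST-like lineage ST/STm) split ~168.8 kya; the Mukojima ecotypes were
# founded by near-synchronous splits from their source ecotypes (Sm from S at
# 81.4 kya, STm from ST at 82.3 kya); S, Sm and STm share a recent population
# reduction at 37.1 kya while SG and ST expanded.
#
# Times and migration magnitudes are main-text estimates.  The SG split time
# is main-text only as "approximately 80 kya"; per-deme sizes and size-change
# magnitudes are supplementary-only and the values below are PLACEHOLDERS.
name: g2
mu: 1.74e-8
populations:
  - {name: S,   island_group: Chichijima, n_diploid: 12, N_current: 1000}
  - {name: Sm,  island_group: Mukojima,   n_diploid: 7,  N_current: 1000}
  - {name: STm, island_group: Mukojima,   n_diploid: 7,  N_current: 1000}
  - {name: ST,  island_group: Hahajima,   n_diploid: 7,  N_current: 5000}
  - {name: SG,  island_group: Hahajima,   n_diploid: 13, N_current: 5000}
events:
  # shared recent reduction of S, Sm, STm at 37.1 kya = 7,420 generations
  # (backward: the size rises to the pre-reduction value)
  - {time: 7420, kind: size_change, source: S,   new_size: 8000, label: Tred}
  - {time: 7420, kind: size_change, source: Sm,  new_size: 8000, label: Tred}
  - {time: 7420, kind: size_change, source: STm, new_size: 8000, label: Tred}
  # recent expansion of the Hahajima ecotypes
  - {time: 7420, kind: size_change, source: SG, new_size: 500, label: Texp}
  - {time: 7420, kind: size_change, source: ST, new_size: 500, label: Texp}
  # SG split (~80 kya scale; exact value supplementary-only)
  - {time: 15600, kind: divergence, source: SG,  sink: S,  label: TSG}
  # Mukojima foundings: Sm from S at 81.4 kya, STm from ST at 82.3 kya
  - {time: 16280, kind: divergence, source: Sm,  sink: S,  label: T2}
  - {time: 16460, kind: divergence, source: STm, sink: ST, label: T3}
  # split of the two ancestral lineages, 168.8 kya = 33,760 generations
  - {time: 33760, kind: divergence, source: ST,  sink: S,  label: T1}
migration:
  # within-island-group pairs only, recent epoch
  t_end: 7420
  symmetric: true
  rates:
    - {from: Sm, to: STm, m: 1.0e-4}  # M = 0.10 at N = 1000
    - {from: ST, to: SG,  m: 4.0e-5}  # M = 0.20 at N = 5000
free_params:
  - {name: T1,   bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T1}]}
  - {name: T2,   bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T2}]}
  - {name: T3,   bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T3}]}
  - {name: TSG,  bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: TSG}]}
  - {name: Tred, bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: Tred}]}
  - name: m_Muk
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: Sm, to: STm}, {kind: migration, from: STm, to: Sm}]
  - name: m_Hah
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: ST, to: SG}, {kind: migration, from: SG, to: ST}]
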