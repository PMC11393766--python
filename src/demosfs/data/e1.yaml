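# Best six-species/ecotype divergence model for the Chichijima + Hahajima
# radiation ("e1"): ecotype ST splits first (~170.7 kya at 5 yr/gen), the
# remaining five species/ecotypes split in a narrow window (72.9-76.9 kya),
# most demes expand at 70.2 kya, and migration is recent and confined to
# within-island-group pairs.
#
# Times and migration magnitudes are main-text estimates.  Per-deme effective
# sizes and expansion magnitudes were published only in supplementary tables:
# the sizes below are PLACEHOLDERS (flagged per the open supplementary gap),
# chosen at a realistic order of magnitude for island tree populations.
name: e1
mu: 1.74e-8
populations:
  - {name: P,  island_group: Chichijima, n_diploid: 14, N_current: 5000}
  - {name: G,  island_group: Chichijima, n_diploid: 14, N_current: 5000}
  - {name: S,  island_group: Chichijima, n_diploid: 12, N_current: 5000}
  - {name: SG, island_group: Hahajima,   n_diploid: 13, N_current: 5000}
  - {name: SD, island_group: Hahajima,   n_diploid: 13, N_current: 5000}
  - {name: ST, island_group: Hahajima,   n_diploid: 7,  N_current: 5000}
events:
  # recent population expansion at 70.2 kya = 14,040 generations (all demes
  # except S and SD); backward in time the size drops to the ancestral value
  - {time: 14040, kind: size_change, source: P,  new_size: 500, label: Texp}
  - {time: 14040, kind: size_change, source: G,  new_size: 500, label: Texp}
  - {time: 14040, kind: size_change, source: SG, new_size: 500, label: Texp}
  - {time: 14040, kind: size_change, source: ST, new_size: 500, label: Texp}
  # near-simultaneous divergences, 72.9-76.9 kya = 14,580-15,380 generations
  - {time: 14580, kind: divergence, source: G,  sink: P,  label: T5}
  - {time: 14840, kind: divergence, source: SD, sink: SG, label: T4}
  - {time: 15120, kind: divergence, source: SG, sink: S,  label: T3}
  - {time: 15380, kind: divergence, source: S,  sink: P,  label: T2}
  # ancient split of ecotype ST, 170.7 kya = 34,140 generations
  - {time: 34140, kind: divergence, source: ST, sink: P,  label: T1}
migration:
  # recent epoch only; forward fractions m = M / N_dest with migrant numbers
  # per generation M inside the estimated 0.020-0.511 range
  t_end: 14040
  symmetric: true
  rates:
    - {from: P,  to: G,  m: 2.0e-5}   # M = 0.10
    - {from: P,  to: S,  m: 4.0e-5}   # M = 0.20
    - {from: G,  to: S,  m: 3.0e-5}   # M = 0.15
    - {from: SG, to: SD, m: 6.0e-5}   # M = 0.30
    - {from: SG, to: ST, m: 2.0e-5}   # M = 0.10
    - {from: SD, to: ST, m: 4.0e-5}   # M = 0.20
free_params:
  - {name: T1, bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T1}]}
  - {name: T2, bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T2}]}
  - {name: T3, bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T3}]}
  - {name: T4, bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T4}]}
  - {name: T5, bounds: [1.0e+2, 1.0e+5], log: true, slots: [{kind: event_time, label: T5}]}
  - name: m_PG
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: P, to: G}, {kind: migration, from: G, to: P}]
  - name: m_PS
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: P, to: S}, {kind: migration, from: S, to: P}]
  - name: m_GS
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: G, to: S}, {kind: migration, from: S, to: G}]
  - name: m_SGSD
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: SG, to: SD}, {kind: migration, from: SD, to: SG}]
  - name: m_SGST
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: SG, to: ST}, {kind: migration, from: ST, to: SG}]
  - name: m_SDST
    bounds: [1.0e-8, 1.0e-1]
    log: true
    slots: [{kind: migration, from: SD, to: ST}, {kind: migration, from: ST, to: SD}]
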