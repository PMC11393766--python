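# Allometric coefficients for the avian seed-dispersal-distance calculator.
#
# distance [km] = flight_speed(mass) [km/h] * retention_time(mass) [min] / 60
# with both components power laws of body mass in grams:
#     retention_time = retention.intercept * mass_g ** retention.exponent   [min]
#     flight_speed   = speed.intercept     * mass_g ** speed.exponent       [km/h]
#
# Coefficients are DATA, not code: they must be transcribed from the cited
# allometric studies (a phylogenetic GLS fit of gut seed-retention time on
# body mass, and the mass^(1/6) cruising-speed scaling for birds).  The
# numbers bundled here are PROVISIONAL literature-anchored values — the exact
# published intercepts must be checked against the sources before using the
# outputs quantitatively; see examples/dispersal_validation.py.
retention:
  intercept: 10.5       # min at 1 g  (PROVISIONAL transcription)
  exponent: 0.25        # PGLS mass scaling of gut retention time
  mass_unit: g
  time_unit: min
  source: "Yoshikawa et al. (2019), PGLS of seed retention time on body mass"
speed:
  intercept: 19.8       # km/h at 1 g (PROVISIONAL transcription)
  exponent: 0.1667      # mass^(1/6) cruising-speed scaling
  mass_unit: g
  speed_unit: km/h
  source: "Tennekes (2009), The Simple Science of Flight, great flight diagram"
species:
  - {name: brown-eared bulbul,   mass_g: 67.0,  note: "Hypsipetes amaurotis"}
  - {name: Japanese wood pigeon, mass_g: 550.0, note: "Columba janthina nitens"}
  - {name: jungle crow,          mass_g: 575.0, note: "Corvus macrorhynchos"}
published_distances_km:
  brown-eared bulbul: 39.7
  Japanese wood pigeon: 88.8
  jungle crow: 110.0
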