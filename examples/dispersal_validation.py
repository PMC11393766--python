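"""Validation sheet for the allometric seed-dispersal calculator.

Evaluates distance = flight_speed(mass) x retention_time(mass) for the three
candidate dispersers of the island *Callicarpa* (brown-eared bulbul, Japanese
wood pigeon, jungle crow) and prints the computed values next to the
published distances (39.7, 88.8 and 110 km).

The bundled coefficient config holds PROVISIONAL literature-anchored values:
reproducing the published numbers to 3 significant figures requires
transcribing the exact intercepts/exponents from the two cited allometric
studies (the PGLS seed-retention fit and the mass^(1/6) flight-speed
scaling) into a coefficient YAML and passing it here.  Until then, expect
the right order of magnitude and ordering, not digit-level agreement.

Usage: python examples/dispersal_validation.py [coefficients.yaml]
"""

import sys

from demosfs.dispersal import bundled_allometry, load_allometry, species_table

if len(sys.argv) > 1:
    am = load_allometry(sys.argv[1])
    _, cfg = bundled_allometry()  # species list + published targets
else:
    am, cfg = bundled_allometry()

table = species_table(cfg["species"], am)
published = cfg.get("published_distances_km", {})

print(f"{'species':24s} {'mass g':>7s} {'speed km/h':>10s} "
      f"{'retention min':>13s} {'computed km':>11s} {'published km':>12s}")
for _, row in table.iterrows():
    pub = published.get(row["name"], float("nan"))
    print(f"{row['name']:24s} {row['mass_g']:7.0f} {row['speed_kmh']:10.1f} "
          f"{row['retention_min']:13.1f} {row['distance_km']:11.1f} {pub:12.1f}")
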