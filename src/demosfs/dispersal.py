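"""Allometric seed-dispersal-distance calculator for avian dispersers.

Long-distance seed dispersal between island groups is attributed to
frugivorous birds; a first-order estimate of how far a bird carries a seed is

    distance = flight speed x gut retention time,

with both components allometric power laws of body mass m (grams):

    retention_time(m) = a_r * m ** b_r   [minutes]
    flight_speed(m)   = a_s * m ** b_s   [km/h]
    distance(m)       = flight_speed(m) * retention_time(m) / 60   [km]

The coefficients are data, not code: they come from published allometric fits
(a phylogenetic GLS of seed retention time on body mass, and the classical
mass^(1/6) cruising-speed scaling) and are supplied through a YAML config
with citation fields.  The calculator never silently invents coefficients —
a missing block is a configuration error.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .models import ModelError

__all__ = [
    "PowerLaw",
    "AllometricModel",
    "load_allometry",
    "bundled_allometry",
    "retention_time",
    "flight_speed",
    "dispersal_distance",
    "species_table",
]

MIN_PER_HOUR = 60.0


@dataclass(frozen=True)
class PowerLaw:
    """y = intercept * mass_g ** exponent."""

    intercept: float
    exponent: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.intercept > 0):
            raise ModelError("power-law intercept must be positive")
        if not (abs(self.exponent) < 10):
            raise ModelError("power-law exponent must be finite and sane")

    def __call__(self, mass_g: float) -> float:
        if not mass_g > 0:
            raise ModelError("body mass must be positive")
        return self.intercept * mass_g ** self.exponent


@dataclass(frozen=True)
class AllometricModel:
    """Body-mass power laws for gut retention time (min) and flight speed
    (km/h), with provenance notes for the transcribed coefficients."""

    retention: PowerLaw
    speed: PowerLaw


def load_allometry(config: dict | str) -> AllometricModel:
    """Build an :class:`AllometricModel` from a YAML path or parsed dict.

    Raises a configuration error when a coefficient block is missing —
    coefficients are transcribed data and there are no silent defaults.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    for block in ("retention", "speed"):
        if block not in config or config[block] is None:
            raise ModelError(f"allometry config missing the {block!r} block")
        for key in ("intercept", "exponent"):
            if key not in config[block]:
                raise ModelError(f"allometry config missing {block}.{key}")
    return AllometricModel(
        retention=PowerLaw(
            float(config["retention"]["intercept"]),
            float(config["retention"]["exponent"]),
            str(config["retention"].get("source", "")),
        ),
        speed=PowerLaw(
            float(config["speed"]["intercept"]),
            float(config["speed"]["exponent"]),
            str(config["speed"].get("source", "")),
        ),
    )


def bundled_allometry() -> tuple[AllometricModel, dict]:
    """The packaged (provisional) coefficient config and its raw dict."""
    text = resources.files("demosfs.data").joinpath(
        "dispersal_coefficients.yaml"
    ).read_text()
    cfg = yaml.safe_load(text)
    return load_allometry(cfg), cfg


def retention_time(body_mass_g: float, am: AllometricModel) -> float:
    """Gut seed-retention time in minutes."""
    return am.retention(body_mass_g)


def flight_speed(body_mass_g: float, am: AllometricModel) -> float:
    """Cruising flight speed in km/h."""
    return am.speed(body_mass_g)


def dispersal_distance(body_mass_g: float, am: AllometricModel) -> dict:
    """Seed dispersal distance in km, with its two components.

    km/h x min -> km uses the exact 1/60 conversion.
    """
    t_min = retention_time(body_mass_g, am)
    v_kmh = flight_speed(body_mass_g, am)
    return {
        "retention_min": t_min,
        "speed_kmh": v_kmh,
        "distance_km": v_kmh * t_min / MIN_PER_HOUR,
    }


def species_table(
    species: list[dict],
    am: AllometricModel,
) -> pd.DataFrame:
    """Evaluate the calculator over a species table.

    ``species`` rows need ``name`` and ``mass_g``; the returned frame carries
    speed (km/h), retention (min) and distance (km) per species.
    """
    rows = []
    for sp in species:
        d = dispersal_distance(float(sp["mass_g"]), am)
        rows.append(
            {
                "name": sp["name"],
                "mass_g": float(sp["mass_g"]),
                "speed_kmh": d["speed_kmh"],
                "retention_min": d["retention_min"],
                "distance_km": d["distance_km"],
            }
        )
    return pd.DataFrame(rows)
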