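"""Bundled model fixtures: the two best divergence models and the study's
sampling layout.

``model_e1`` is the best six-species/ecotype model for the Chichijima and
Hahajima radiation (ecotype ST splits ~170.7 kya, the other five
species/ecotypes split near-simultaneously at 72.9-76.9 kya, recent
within-island-group migration, expansion at 70.2 kya).  ``model_g2`` is the
best five-ecotype model adding the Mukojima Islands (two ancestral lineages
split ~168.8 kya; Sm and STm founded from S and ST at 81.4/82.3 kya; shared
reduction of S/Sm/STm at 37.1 kya).

Event times in the YAML fixtures are main-text point estimates converted at
5 years per generation; effective sizes are placeholders (the per-deme
estimates were published only in supplementary tables).
"""

from importlib import resources

import yaml

from .models import DemographicModel, build_model

__all__ = ["model_e1", "model_g2", "STUDY_POPULATIONS", "study_popmap"]


def _load(name: str) -> DemographicModel:
    text = resources.files("demosfs.data").joinpath(name).read_text()
    return build_model(yaml.safe_load(text))


def model_e1() -> DemographicModel:
    """Best six-species/ecotype divergence model (Chichijima + Hahajima)."""
    return _load("e1.yaml")


def model_g2() -> DemographicModel:
    """Best five-ecotype divergence model (incl. the Mukojima ecotypes)."""
    return _load("g2.yaml")


# The 14 sampled populations (id, island group, species/ecotype group,
# diploids sampled).  Populations of one group on different islands of the
# same island group share a genetic cluster and are merged by the popmap.
STUDY_POPULATIONS = [
    ("Pa", "Chichijima", "P", 7),
    ("Pc", "Chichijima", "P", 7),
    ("Ga", "Chichijima", "G", 7),
    ("Gc", "Chichijima", "G", 7),
    ("STm", "Mukojima", "STm", 7),
    ("Sm", "Mukojima", "Sm", 7),
    ("Sa", "Chichijima", "S", 5),
    ("Sc", "Chichijima", "S", 7),
    ("SGh", "Hahajima", "SG", 7),
    ("SGi", "Hahajima", "SG", 6),
    ("SDh", "Hahajima", "SD", 7),
    ("SDi", "Hahajima", "SD", 6),
    ("STh", "Hahajima", "ST", 7),
    ("SHh", "Hahajima", "SH", 7),
]


def study_popmap() -> dict[str, str]:
    """Population id -> species/ecotype group for the 14 sampled populations."""
    return {pid: group for pid, _isl, group, _n in STUDY_POPULATIONS}
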