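import numpy as np
import pytest

from demosfs.coalsim import GenotypeMatrix, SiteRecord
from demosfs.models import (
    DemographicEvent,
    DemographicModel,
    FreeParameter,
    Population,
)


@pytest.fixture
def single_deme():
    """One constant-size deme, 3 diploids (6 haplotypes)."""
    return DemographicModel((Population("A", "X", 3, 2000),), ())


def make_two_deme(t_split=2000.0, n_dip=4, N=2000.0, free_time=True):
    """Clean two-deme split, time optionally a free parameter."""
    free = (
        (FreeParameter("T", (1e2, 1e5), True, ({"kind": "event_time", "label": "T"},)),)
        if free_time
        else ()
    )
    return DemographicModel(
        (Population("A", "X", n_dip, N), Population("B", "X", n_dip, N)),
        (DemographicEvent(t_split, "divergence", "B", "A", label="T"),),
        free_params=free,
    )


@pytest.fixture
def two_deme():
    return make_two_deme()


def make_matrix(genotypes, pops_per_ind, chrom_prefix="c"):
    """Hand-built GenotypeMatrix from a nested list of genotype codes."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = geno.shape
    sites = [
        SiteRecord(chrom=f"{chrom_prefix}{i}", pos=1, is_variable=bool((geno[i] > 0).any()))
        for i in range(n_sites)
    ]
    individuals = [f"ind{j}" for j in range(n_ind)]
    return GenotypeMatrix(sites, individuals, list(pops_per_ind), geno)
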