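"""Synthetic ddRAD genotypes and Monte-Carlo expected SFS under a demographic model.

This is both the synthetic-data engine (``simulate_genotypes`` emulates the
filtered genotype matrix a ddRAD pipeline would deliver) and the expected-SFS
engine the composite-likelihood fitter calls on every likelihood evaluation
(``expected_sfs_pairs``).

Loci are unlinked: every site draws an independent genealogy, matching
SFS-only inference where linkage carries no information.  Mutation is
infinite-sites at rate ``mu * locus_length`` per lineage per generation
(default locus length 51 bp, a short single-end RAD read); by default each
locus retains at most one SNP — its first mutation — mirroring common
one-SNP-per-RAD-locus conventions.  Diploids are formed by pairing
consecutive haplotypes within a deme (Hardy-Weinberg implied).

The expected SFS is estimated from branch lengths rather than sampled
mutations: a genealogy with total length L contributes probability mass
``(1 - exp(-mu*l*L)) * L_c / L`` to the cell whose branch class is c and
``exp(-mu*l*L)`` to the monomorphic cell.  This averages over mutation
placement analytically and therefore has strictly lower Monte-Carlo variance
than mutation sampling, while estimating the same per-site cell
probabilities the genotype simulator realises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _engine
from .models import DemographicModel, ModelError

__all__ = [
    "SiteRecord",
    "GenotypeMatrix",
    "MISSING",
    "simulate_genotypes",
    "expected_sfs",
    "expected_sfs_pairs",
    "expected_sfs_1d",
    "apply_missingness",
    "fold_2d",
    "fold_1d",
    "write_vcf",
    "write_popmap",
]

MISSING = -1  # genotype code for a missing diploid call
DEFAULT_LOCUS_LENGTH = 51


@dataclass(frozen=True)
class SiteRecord:
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "T"
    is_variable: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ModelError("site pos must be >= 1")


@dataclass
class GenotypeMatrix:
    """Sites x diploid individuals, alt-allele counts in {0, 1, 2, MISSING}."""

    sites: list[SiteRecord]
    individuals: list[str]
    populations: list[str]  # per-individual population label
    genotypes: np.ndarray  # int8 (n_sites, n_individuals)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.individuals)):
            raise ModelError("genotype matrix dimensions inconsistent")
        if len(self.populations) != len(self.individuals):
            raise ModelError("every individual needs a population label")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ModelError("genotype codes must be in {0, 1, 2, missing}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def pop_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations) == pop)
        if idx.size == 0:
            raise ModelError(f"no individuals in population {pop!r}")
        return idx

    def popmap(self) -> dict[str, str]:
        return dict(zip(self.individuals, self.populations))

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.arange(self.n_sites)[mask_or_index]
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            individuals=list(self.individuals),
            populations=list(self.populations),
            genotypes=self.genotypes[idx].copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.individuals == other.individuals
            and self.populations == other.populations
            and np.array_equal(self.genotypes, other.genotypes)
        )


# ---------------------------------------------------------------------------
# model flattening


def _flatten(model: DemographicModel):
    names = model.pop_names
    D = len(names)
    samples = np.array([2 * p.n_diploid for p in model.populations], np.int64)
    sizes = np.array([p.N_current for p in model.populations], np.float64)
    idx = {n: k for k, n in enumerate(names)}
    evs = sorted(model.events, key=lambda e: e.time)  # stable
    ev_time = np.array([e.time for e in evs], np.float64)
    ev_kind = np.array(
        [0 if e.kind == "divergence" else 1 for e in evs], np.int8
    )
    ev_a = np.array([idx[e.source] for e in evs], np.int64)
    ev_b = np.array(
        [idx[e.sink] if e.sink is not None else -1 for e in evs], np.int64
    )
    ev_size = np.array(
        [e.new_size if e.new_size is not None else 0.0 for e in evs], np.float64
    )
    if model.migration is not None and model.migration.rates:
        mig_end = float(model.migration.t_end)
        mig = model.migration.backward_matrix(names)
    else:
        mig_end = 0.0
        mig = np.zeros((D, D))
    return samples, sizes, ev_time, ev_kind, ev_a, ev_b, ev_size, mig_end, mig


def _seed32(seed: int) -> int:
    return int(seed) % 2147483647


# ---------------------------------------------------------------------------
# folding


def fold_2d(table: np.ndarray) -> np.ndarray:
    """Fold a joint spectrum to minor-allele orientation on the pooled pair.

    Cells whose pooled derived/ALT count exceeds half the pooled sample size
    are reflected onto their complement; exact 50:50 ties keep the ALT
    orientation (deterministic, single-counted)."""
    na = table.shape[0] - 1
    nb = table.shape[1] - 1
    out = np.zeros_like(np.asarray(table, dtype=float))
    for i in range(na + 1):
        for j in range(nb + 1):
            if 2 * (i + j) > na + nb:
                out[na - i, nb - j] += table[i, j]
            else:
                out[i, j] += table[i, j]
    return out


def fold_1d(vec: np.ndarray) -> np.ndarray:
    n = len(vec) - 1
    out = np.zeros(n + 1, dtype=float)
    for i in range(n + 1):
        if 2 * i > n:
            out[n - i] += vec[i]
        else:
            out[i] += vec[i]
    return out


# ---------------------------------------------------------------------------
# public operations


def simulate_genotypes(
    model: DemographicModel,
    n_sites: int,
    *,
    locus_length: int = DEFAULT_LOCUS_LENGTH,
    seed: int = 0,
    one_snp_per_locus: bool = True,
) -> GenotypeMatrix:
    """Simulate ``n_sites`` unlinked RAD loci worth of diploid genotypes.

    The returned matrix includes monomorphic loci (``is_variable=False``),
    the class the composite likelihood's (0, 0) cell counts.
    """
    if n_sites < 1:
        raise ModelError("n_sites must be >= 1")
    arrs = _flatten(model)
    samples = arrs[0]
    if samples.sum() == 0:
        raise ModelError("model samples no demes")
    names = model.pop_names
    individuals: list[str] = []
    populations: list[str] = []
    ind_of_hap = np.empty(samples.sum(), np.int64)
    h = 0
    ind = 0
    for d, name in enumerate(names):
        n_dip = samples[d] // 2
        for i in range(n_dip):
            individuals.append(f"{name}_{i + 1}")
            populations.append(name)
            ind_of_hap[h] = ind
            ind_of_hap[h + 1] = ind
            h += 2
            ind += 1
    mu_l = model.mu * locus_length
    cap = n_sites if one_snp_per_locus else max(2 * n_sites, n_sites + 64)
    while True:
        geno = np.zeros((cap, len(individuals)), np.int8)
        locus_id = np.empty(cap, np.int64)
        ns = _engine._simulate_loci(
            *arrs, mu_l, n_sites, _seed32(seed),
            1 if one_snp_per_locus else 0,
            ind_of_hap, geno, locus_id,
        )
        if ns == -1:
            raise ModelError("model is structurally stuck (isolated lineages)")
        if ns == -2:
            cap *= 2
            continue
        break
    geno = geno[:ns]
    locus_id = locus_id[:ns]
    sites: list[SiteRecord] = []
    within: dict[int, int] = {}
    alt_any = (geno > 0).any(axis=1)
    for row in range(ns):
        loc = int(locus_id[row])
        k = within.get(loc, 0) + 1
        within[loc] = k
        sites.append(
            SiteRecord(
                chrom=f"locus{loc}",
                pos=k,
                ref="A",
                alt="T",
                is_variable=bool(alt_any[row]),
            )
        )
    return GenotypeMatrix(sites, individuals, populations, geno)


def expected_sfs_pairs(
    model: DemographicModel,
    pairs: Sequence[tuple[str, str]],
    *,
    n_sims: int = 100_000,
    seed: int = 0,
    locus_length: int = DEFAULT_LOCUS_LENGTH,
    fold: bool = True,
) -> dict[tuple[str, str], np.ndarray]:
    """Monte-Carlo expected 2D-mSFS probability tables for several pairs.

    All pairs share the same simulated genealogies (one pass over ``n_sims``
    genealogies), so a model with P pairs costs barely more than one pair.
    Each table sums to exactly 1 and includes the monomorphic (0, 0) cell.
    """
    if n_sims < 1:
        raise ModelError("n_sims must be >= 1")
    names = model.pop_names
    idx = {n: k for k, n in enumerate(names)}
    for a, b in pairs:
        if a not in idx or b not in idx:
            raise ModelError(f"pair ({a}, {b}) references unknown deme")
    arrs = _flatten(model)
    samples = arrs[0]
    pair_arr = np.array([[idx[a], idx[b]] for a, b in pairs], np.int64)
    sizes = [
        (samples[pair_arr[p, 0]] + 1) * (samples[pair_arr[p, 1]] + 1)
        for p in range(len(pairs))
    ]
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
    flat = np.zeros(int(np.sum(sizes)), np.float64)
    mu_l = model.mu * locus_length
    n_ok = _engine._pair_tables(
        *arrs, pair_arr, offsets, mu_l, int(n_sims), _seed32(seed), flat
    )
    if n_ok == 0:
        raise ModelError("no genealogy could be simulated under this model")
    out: dict[tuple[str, str], np.ndarray] = {}
    for p, (a, b) in enumerate(pairs):
        na1 = samples[pair_arr[p, 0]] + 1
        nb1 = samples[pair_arr[p, 1]] + 1
        tab = flat[offsets[p]: offsets[p] + na1 * nb1].reshape(na1, nb1) / n_ok
        out[(a, b)] = fold_2d(tab) if fold else tab
    return out


def expected_sfs(
    model: DemographicModel,
    pair: tuple[str, str],
    *,
    n_sims: int = 100_000,
    seed: int = 0,
    locus_length: int = DEFAULT_LOCUS_LENGTH,
    fold: bool = True,
) -> np.ndarray:
    """Expected folded 2D-mSFS probability table for one population pair."""
    a, b = pair
    if a == b:
        raise ModelError("expected_sfs needs two distinct demes; see expected_sfs_1d")
    return expected_sfs_pairs(
        model, [pair], n_sims=n_sims, seed=seed,
        locus_length=locus_length, fold=fold,
    )[pair]


def expected_sfs_1d(
    model: DemographicModel,
    pop: str,
    *,
    n_sims: int = 100_000,
    seed: int = 0,
    locus_length: int = DEFAULT_LOCUS_LENGTH,
    fold: bool = True,
) -> np.ndarray:
    """Degenerate one-population call: expected (folded) 1D SFS."""
    tab = expected_sfs_pairs(
        model, [(pop, pop)], n_sims=n_sims, seed=seed,
        locus_length=locus_length, fold=False,
    )[(pop, pop)]
    vec = np.diag(tab).copy()
    return fold_1d(vec) if fold else vec


def apply_missingness(
    g: GenotypeMatrix,
    rate: float | Mapping[str, float],
    seed: int = 0,
) -> GenotypeMatrix:
    """Independently knock out genotypes with the given probability
    (scalar, or per-population mapping)."""
    if isinstance(rate, Mapping):
        per_ind = np.array([rate[p] for p in g.populations], float)
    else:
        per_ind = np.full(g.n_individuals, float(rate))
    if ((per_ind < 0) | (per_ind > 1)).any():
        raise ModelError("missingness rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(g.genotypes.shape) < per_ind[None, :]
    geno = g.genotypes.copy()
    geno[mask] = MISSING
    return GenotypeMatrix(list(g.sites), list(g.individuals), list(g.populations), geno)


# ---------------------------------------------------------------------------
# VCF / popmap output (the dialect module sfs reads back)

_GT = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    g: GenotypeMatrix,
    path,
    *,
    monomorphic_alt: bool = False,
    extra_header: Sequence[str] = (),
) -> None:
    """Write VCF 4.2 with unphased diploid genotypes.

    Monomorphic records carry ``ALT=.`` by default, or an invariant ALT
    allele when ``monomorphic_alt`` is set.
    """
    chroms: list[str] = []
    for s in g.sites:
        if not chroms or chroms[-1] != s.chrom:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=demosfs\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for c in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={c},length=1000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals)
            + "\n"
        )
        for row, site in enumerate(g.sites):
            alt = site.alt if (site.is_variable or monomorphic_alt) else "."
            gts = "\t".join(_GT[int(x)] for x in g.genotypes[row])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_popmap(g: GenotypeMatrix, path) -> None:
    """Two-column individual -> population TSV."""
    with open(path, "w") as fh:
        for ind, pop in zip(g.individuals, g.populations):
            fh.write(f"{ind}\t{pop}\n")
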