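"""Site filtering and folded 2D minor-allele SFS construction.

The filters reproduce the Stacks ``populations`` site-selection rules applied
to a RAD-seq genotype matrix (per-population genotyping rate ``-r``, number of
genotyped populations ``-p``, minimum minor-allele count ``--min-mac``,
maximum observed heterozygosity ``--max-obs-het``) plus an optional
across-all-individuals genotyping-rate floor.

The 2D-mSFS counts SNPs by minor-allele copy number jointly in two
populations.  Missing genotypes are completed by bootstrapping within the
population: absent haplotypes are drawn i.i.d. with replacement from the
alleles observed in that population at that site, so the completed sample
always reaches the nominal haploid size and the spectrum keeps a fixed shape.
The minor allele is decided on the pooled, completed pair; exact 50:50 pooled
ties keep the ALT allele (a deterministic, documented convention — integer
counts, no half-cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coalsim import MISSING, GenotypeMatrix, SiteRecord
from .models import ModelError

__all__ = [
    "FilterConfig",
    "SFS2D",
    "filter_sites",
    "fill_missing_bootstrap",
    "build_2d_msfs",
    "read_vcf",
    "read_popmap",
    "write_sfs",
    "read_sfs",
    "write_fsc_obs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Stacks-style site filters.

    r: minimum genotyping rate within a population for that population to
       count as "genotyped"; p: number of populations that must be genotyped;
    min_mac: minimum pooled minor-allele count; max_obs_het: maximum observed
    heterozygote fraction; overall_rate: optional across-all-individuals
    genotyping-rate floor (0.3 / 0.5 / 0.8 in typical use).
    """

    r: float = 0.8
    p: int = 1
    min_mac: int = 1
    max_obs_het: float = 0.5
    overall_rate: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("r", self.r), ("max_obs_het", self.max_obs_het)):
            if not (0.0 <= v <= 1.0):
                raise ModelError(f"filter {name} must be in [0, 1]")
        if self.overall_rate is not None and not (0.0 <= self.overall_rate <= 1.0):
            raise ModelError("overall_rate must be in [0, 1]")
        if self.min_mac < 0:
            raise ModelError("min_mac must be >= 0")
        if self.p < 1:
            raise ModelError("p must be >= 1")


@dataclass
class SFS2D:
    """Folded 2D minor-allele SFS for one population pair.

    ``counts[i, j]`` is the number of sites with i minor-allele copies in
    ``pair[0]`` (haploid size n1) and j in ``pair[1]``; cell (0, 0) holds the
    monomorphic sites.  ``n_excluded`` counts sites dropped because one
    population had no genotyped individual.
    """

    pair: tuple[str, str]
    n1: int
    n2: int
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ModelError("SFS2D counts shape inconsistent with sample sizes")
        if (self.counts < 0).any():
            raise ModelError("SFS2D counts must be nonnegative")
        i = np.arange(self.n1 + 1)[:, None]
        j = np.arange(self.n2 + 1)[None, :]
        above = 2 * (i + j) > self.n1 + self.n2
        if self.counts[above].any():
            raise ModelError("SFS2D has mass above the folding diagonal")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def transpose(self) -> "SFS2D":
        return SFS2D(
            pair=(self.pair[1], self.pair[0]),
            n1=self.n2,
            n2=self.n1,
            counts=self.counts.T.copy(),
            n_excluded=self.n_excluded,
        )


# ---------------------------------------------------------------------------
# filtering


def filter_sites(g: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Apply the genotyping-rate / MAC / heterozygosity filters; keeps site
    and individual order.  Idempotent."""
    geno = g.genotypes
    typed = geno != MISSING
    n_typed = typed.sum(axis=1)

    pop_ok = np.zeros(g.n_sites, dtype=int)
    for pop in g.pop_names:
        idx = g.pop_indices(pop)
        rate = typed[:, idx].mean(axis=1)
        pop_ok += rate >= cfg.r
    keep = pop_ok >= cfg.p

    alt = np.where(typed, geno, 0).sum(axis=1)
    tot = 2 * n_typed
    mac = np.minimum(alt, tot - alt)
    keep &= (mac >= cfg.min_mac) & (n_typed > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_typed > 0, (geno == 1).sum(axis=1) / n_typed, 1.0)
    keep &= het <= cfg.max_obs_het

    if cfg.overall_rate is not None:
        keep &= typed.mean(axis=1) >= cfg.overall_rate
    return g.take_sites(keep)


# ---------------------------------------------------------------------------
# missing-data bootstrap


class AllMissingError(ModelError):
    """Raised when a site has no genotyped individual in a population."""


def fill_missing_bootstrap(
    genotypes: np.ndarray,
    target_haploid: int,
    seed,
    *,
    genotype_level: bool = False,
) -> np.ndarray:
    """Complete one population's alleles at one site to ``target_haploid``
    haplotypes.

    ``genotypes`` are the population's diploid codes at the site (MISSING
    allowed).  Observed alleles are kept; the shortfall is drawn i.i.d. with
    replacement from the observed alleles (haplotype level, the default) or
    from the observed diploid genotypes (``genotype_level``).  Returns the
    completed multiset as a sorted array of 0/1 alleles.
    """
    geno = np.asarray(genotypes)
    obs = geno[geno != MISSING]
    if obs.size == 0:
        raise AllMissingError("all genotypes missing in population at site")
    # observed haplotypes: genotype g contributes g copies of 1, 2-g of 0
    ones = int(obs.sum())
    haps = np.concatenate([np.ones(ones, dtype=np.int8),
                           np.zeros(2 * obs.size - ones, dtype=np.int8)])
    n_fill = target_haploid - haps.size
    if n_fill < 0:
        raise ModelError("target haploid size smaller than observed alleles")
    rng = np.random.default_rng(seed)
    if n_fill == 0:
        return np.sort(haps)
    if genotype_level:
        if n_fill % 2:
            raise ModelError("genotype-level fill needs an even shortfall")
        draws = rng.choice(obs, size=n_fill // 2, replace=True)
        fill_ones = int(draws.sum())
        fill = np.concatenate([np.ones(fill_ones, dtype=np.int8),
                               np.zeros(n_fill - fill_ones, dtype=np.int8)])
    else:
        fill = rng.choice(haps, size=n_fill, replace=True)
    return np.sort(np.concatenate([haps, fill]))


# ---------------------------------------------------------------------------
# 2D-mSFS construction


def build_2d_msfs(
    g: GenotypeMatrix,
    popA: str,
    popB: str,
    seed: int = 0,
    *,
    genotype_level: bool = False,
) -> SFS2D:
    """Folded 2D minor-allele SFS for (popA, popB), monomorphic cell included.

    Missing data are completed per site and per population by
    :func:`fill_missing_bootstrap`; the per-site generator is seeded from
    ``(seed, site index, population index)`` so the result is reproducible
    and identical whichever way round the pair is requested.  Sites where a
    population has no genotyped individual are excluded and counted in
    ``n_excluded``.
    """
    if popA == popB:
        raise ModelError("build_2d_msfs needs two distinct populations")
    idxA = g.pop_indices(popA)
    idxB = g.pop_indices(popB)
    pops = g.pop_names
    pA, pB = pops.index(popA), pops.index(popB)
    n1, n2 = 2 * idxA.size, 2 * idxB.size
    geno = g.genotypes
    missA = (geno[:, idxA] == MISSING).any(axis=1)
    missB = (geno[:, idxB] == MISSING).any(axis=1)

    aA = np.where(geno[:, idxA] == MISSING, 0, geno[:, idxA]).sum(axis=1)
    aB = np.where(geno[:, idxB] == MISSING, 0, geno[:, idxB]).sum(axis=1)
    aA = aA.astype(np.int64)
    aB = aB.astype(np.int64)
    ok = np.ones(g.n_sites, dtype=bool)

    n_excluded = 0
    for s in np.flatnonzero(missA | missB):
        try:
            if missA[s]:
                aA[s] = int(
                    fill_missing_bootstrap(
                        geno[s, idxA], n1, [seed, int(s), pA],
                        genotype_level=genotype_level,
                    ).sum()
                )
            if missB[s]:
                aB[s] = int(
                    fill_missing_bootstrap(
                        geno[s, idxB], n2, [seed, int(s), pB],
                        genotype_level=genotype_level,
                    ).sum()
                )
        except AllMissingError:
            ok[s] = False
            n_excluded += 1
    if n_excluded:
        logger.info(
            "pair (%s, %s): %d sites excluded (all genotypes missing in one population)",
            popA, popB, n_excluded,
        )

    aA, aB = aA[ok], aB[ok]
    pooled = aA + aB
    flip = 2 * pooled > n1 + n2
    iA = np.where(flip, n1 - aA, aA)
    iB = np.where(flip, n2 - aB, aB)
    counts = np.zeros((n1 + 1, n2 + 1))
    np.add.at(counts, (iA, iB), 1.0)
    return SFS2D(pair=(popA, popB), n1=n1, n2=n2, counts=counts, n_excluded=n_excluded)


def build_all_pairs(
    g: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    seed: int = 0,
) -> dict[tuple[str, str], SFS2D]:
    return {pair: build_2d_msfs(g, *pair, seed=seed) for pair in pairs}


# ---------------------------------------------------------------------------
# I/O


def read_popmap(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ind, pop = line.split("\t")[:2]
            out[ind] = pop
    return out


def read_vcf(path, popmap: Mapping[str, str] | str) -> GenotypeMatrix:
    """Read a VCF 4.2 genotype matrix (the coalsim dialect).

    Multi-allelic records are skipped with a logged count; individuals not in
    the popmap raise.
    """
    from cyvcf2 import VCF

    if isinstance(popmap, (str, bytes)) or hasattr(popmap, "__fspath__"):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    missing_pop = [s for s in individuals if s not in popmap]
    if missing_pop:
        raise ModelError(f"individuals absent from popmap: {missing_pop[:5]}")
    populations = [popmap[s] for s in individuals]
    sites: list[SiteRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) > 1:
            n_multi += 1
            continue
        alt = v.ALT[0] if v.ALT else "."
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0/1/2, 3=unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        sites.append(
            SiteRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt if alt != "." else "T",
                # dialect rule: a present ALT marks the record variable
                is_variable=bool(v.ALT) and alt != ".",
            )
        )
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    geno = (
        np.vstack(rows)
        if rows
        else np.empty((0, len(individuals)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, individuals, populations, geno)


def write_sfs(sfs: SFS2D, path, *, extra_comments: Sequence[str] = ()) -> None:
    """Labelled TSV matrix, rows = pair[0] minor-copy classes."""
    with open(path, "w") as fh:
        for line in extra_comments:
            fh.write(f"# {line}\n")
        fh.write(
            f"# 2D-mSFS pair={sfs.pair[0]},{sfs.pair[1]} "
            f"n1={sfs.n1} n2={sfs.n2} excluded={sfs.n_excluded}\n"
        )
        fh.write("\t".join([""] + [f"{sfs.pair[1]}_{j}" for j in range(sfs.n2 + 1)]) + "\n")
        for i in range(sfs.n1 + 1):
            row = "\t".join(repr(float(x)) for x in sfs.counts[i])
            fh.write(f"{sfs.pair[0]}_{i}\t{row}\n")


def read_sfs(path) -> SFS2D:
    meta: dict[str, str] = {}
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            if "2D-mSFS" in line:
                meta = dict(
                    kv.split("=", 1)
                    for kv in line.lstrip("# ").split()
                    if "=" in kv
                )
            line = fh.readline()
        # `line` now holds the column-label row
        rows = [
            [float(x) for x in ln.rstrip("\n").split("\t")[1:]] for ln in fh
        ]
    a, b = meta["pair"].split(",")
    return SFS2D(
        pair=(a, b),
        n1=int(meta["n1"]),
        n2=int(meta["n2"]),
        counts=np.array(rows),
        n_excluded=int(meta.get("excluded", 0)),
    )


def write_fsc_obs(sfs: SFS2D, path) -> None:
    """fastsimcoal2 joint minor-allele observed-SFS text layout
    (``_jointMAFpop1_0.obs``: rows = second population, cols = first)."""
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t" + "\t".join(f"d0_{j}" for j in range(sfs.n1 + 1)) + "\n")
        for i in range(sfs.n2 + 1):
            row = "\t".join(str(float(sfs.counts[j, i])) for j in range(sfs.n1 + 1))
            fh.write(f"d1_{i}\t{row}\n")
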