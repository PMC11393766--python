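# Methods

## The inference problem

The package targets demographic inference for small sets (2–6) of closely
related taxa genotyped at thousands of short, effectively unlinked RAD loci:
which divergence ordering relates the taxa, when the splits happened, whether
population sizes changed recently, and how much recent gene flow connects
taxa that share an island group. All information is taken from pairwise
folded two-dimensional minor-allele site frequency spectra (2D-mSFS),
including the monomorphic class, which anchors the absolute mutation-rate
scale and therefore absolute times.

## Demographic model

A model is a list of demes with diploid effective sizes, a list of events in
generations backward from the present — divergence (all lineages of a source
deme relocate into a sink deme) and size change (the deme's size for times
older than the event) — and one recent migration epoch `[0, t_end)`.
Migration is configured forward in time: `m[i→j]` is the per-generation
fraction of deme *j* replaced by migrants from deme *i*. Backward in time the
same number is the probability that a lineage sampled in *j* had its parent
in *i*, which is what the simulator uses; the identity is exact because the
forward fraction *is* the per-generation ancestry proportion. Gene flow is
only legal within an island group (demes on different island groups are
separated by open sea), and only in the recent epoch.

Free parameters (times, sizes, migration fractions) bind to model slots by
event label, so one parameter can drive several events — e.g. a shared
population-reduction time across three demes. Where the merge structure
alone does not force an event ordering (two clades joining the same sink),
explicit `time_order` constraints keep candidate topologies honest during
optimization.

Times are internally in generations; conversion to years (default 5
years/generation, a shrub/tree generation time) happens only at I/O
boundaries. The default mutation rate, 1.74 × 10⁻⁸ per site per generation,
is a published woody-plant estimate.

## Coalescent engine

Each locus draws an independent genealogy from the structured coalescent
with piecewise-constant rates: coalescence at rate k(k−1)/(4N) per deme,
migration of each lineage at its backward rate while the recent epoch lasts,
with exponential waiting times between events (the continuous-time limit of
the per-generation process; error is O(m² + 1/N²) and negligible for the
rates involved here). The discrete event times (divergences, size changes,
epoch end) partition time into intervals handled exactly.

Mutation is infinite-sites with opportunity μℓ per lineage-generation
(ℓ = 51 bp, a short single-end RAD read). By default a locus keeps at most
one SNP — its first mutation — matching one-SNP-per-RAD-locus conventions; a
switch retains every mutation as its own site. Diploids pair consecutive
haplotypes within a deme (Hardy–Weinberg implied), and output is plain
VCF 4.2 plus a two-column popmap.

For the likelihood the engine computes expected SFS tables by branch-length
weighting instead of sampling mutations: a genealogy of total length L adds
`(1 − e^{−μℓL})·len/L` to the cell of each branch (classified by descendant
counts in the pair) and `e^{−μℓL}` to the monomorphic cell. This averages
over mutation placement analytically, so each pair's table sums to one per
genealogy and the Monte-Carlo variance is far below mutation sampling at the
same number of genealogies. All pairs share one stream of genealogies, so a
15-pair model costs little more than one pair.

Every genealogy is seeded as `base_seed + locus index`, giving three
properties at once: bitwise reproducibility, common random numbers across
parameter values (the likelihood surface is smooth in θ), and
parallel-safety.

## 2D-mSFS construction and filters

Sites are filtered with the standard RAD-seq rules: a site must be genotyped
in ≥ r of the individuals of each of ≥ p populations (defaults r = 0.8, p as
chosen), carry pooled minor-allele count ≥ min_mac (default 1), show observed
heterozygosity ≤ 0.5, and optionally meet an across-all-individuals
genotyping-rate floor (0.3/0.5/0.8). Filtering is idempotent and
order-preserving.

Missing genotypes are completed per site and per population by bootstrap:
the absent haplotypes are drawn i.i.d. with replacement from the alleles
observed in that population at that site (a genotype-level variant draws
whole diploid genotypes). The per-site generator is seeded from (master
seed, site index, population index), so spectra are reproducible and
identical whichever way round a pair is requested. A site with no genotyped
individual in a population is excluded for that pair and counted, never
silently dropped. The minor allele is decided on the pooled completed pair;
exact 50:50 ties keep the ALT orientation, and diagonal fold ties are
counted once (deterministic integer counts rather than half-cells).

## Composite likelihood and ECM

lnL(θ) = Σ_pairs Σ_cells n(i,j)·ln max(p(i,j|θ), p_min) with
p_min = 1/(10·n_sims) guarding zero simulated cells (natural log throughout;
AIC = 2k − 2 lnL, and base choice cannot change an AIC ranking). Pairs
overlap in sites, so this is a composite likelihood: its argmax is
consistent but its curvature understates uncertainty — hence parametric
bootstrap rather than Hessian-based intervals. A flag drops the monomorphic
cell and renormalizes for SNP-only data.

Maximization runs from `n_starts` random log-uniform starting points
(default bounds: sizes 10²–10⁶, times 10²–10⁵ generations, migration
fractions 10⁻⁸–10⁻¹; they bracket any plausible estimate for this system).
Each of `n_cycles` cycles performs a bounded Brent search on each free
parameter in declaration order, on log scale, restricted to the interval
where the event ordering stays feasible given the other parameters; a
proposal is accepted only if it improves the current likelihood. Full-scale
defaults are 50 starts / 40 cycles / 10⁵ simulations per evaluation
(bootstrap refits: 15 cycles from the fitted values); the tests and the
acceptance experiments run desk-scale versions.

Common random numbers are shared **within** a cycle and redrawn **across**
cycles (default `crn="cycle"`). A fixed surface (`crn="run"`) makes the
cycle trace provably non-decreasing, but its Monte-Carlo realization noise
shifts the argmax; redrawing each cycle turns that bias into zero-mean
jitter. Because per-cycle surfaces carry large additive seed-to-seed lnL
offsets, configurations from different starts or cycles are never compared
on their own surfaces: the trailing-half cycle states of every start, plus
their log-scale means (iterate averaging; pairwise order constraints
survive the mean because they hold cycle-wise), are scored on one shared
surface at `refine_factor` (default 4) times the per-cycle simulation
count, and the winner gets one final conditional-maximization pass on that
high-precision surface (coarse-to-fine). On recovery experiments this
pipeline reproduces the profile-likelihood optimum to within the
data-draw's own uncertainty.

## Model selection and the stepwise ladder

`enumerate_candidates` generates every rooted divergence ordering of a taxon
set, including multifurcations — a polytomy is exactly tied divergence
times, the hard-simultaneity reading; fitted separate times with a narrow
spread are the soft reading, assessed post hoc. Counts grow quickly (4
orderings for 3 taxa, 26 for 4), so larger steps are constrained by the
clades won at earlier steps, mirroring the sequential 3→6-taxon
model-building ladder; `stepwise_search` emits a machine-readable path
(winner and ΔAIC table per step). AIC ties prefer fewer parameters, then
lexicographic model id.

## Parametric bootstrap and goodness of fit

Bootstrap replicates simulate full genotype datasets at the fitted
parameters (same number of loci as observed), rebuild all pair spectra, and
refit from the fitted values with the lighter schedule; the 2.5%/97.5%
percentile interval of the replicate estimates (linear interpolation) is the
95% CI. Failed refits are logged and dropped. Goodness of fit reports
per-cell Pearson residuals (n − E)/√E with E = total·p plus their sum of
squares, and can render observed/expected/residual heatmaps.

## Bundled models and the synthetic study design

`catalog` ships the two best published divergence models as YAML fixtures.
The synthetic study design follows the real sampling: 14 island populations
of 5–7 diploids merged by popmap into species/ecotype groups (P:14, G:14,
S:12, SG:13, SD:13, ST:7, Sm:7, STm:7 diploids), six demes for e1 and five
for g2. Event times and the migrant-number range (0.020–0.511 per
generation) are main-text values; **per-deme effective sizes and size-change
magnitudes are placeholders** (the published values live in supplementary
tables): constant-size demes at N = 5,000 with ancestral sizes 500 after the
shared expansion, and reduced demes at N = 1,000 against a pre-reduction
8,000. The g2 SG-split time is set to 78 kya inside the "approximately 80
kya" window the main text gives. These placeholders affect absolute
information content, not the correctness claims the tests make.

What the generator deliberately omits: genotyping error, allele dropout and
paralog collapse, linkage within loci, and any ascertainment beyond the
implemented filters. Passing recovery tests therefore demonstrates internal
consistency of simulation + spectra + likelihood + optimization at the
study's sampling design — not robustness to the technical artefacts of real
ddRAD data.

## Desk-scale experiment sizes

The self-consistency recovery experiments (also run by
`scripts/acceptance.py`) use 50,000 loci of observed data, ≈5,000 simulated
genealogies per likelihood evaluation, 3 random starts and 10 ECM cycles,
with times free and sizes/migration fixed at truth; the migration-bound
experiment runs 10 seeded fits (alternating e1/g2) at 20,000 loci, 2,500
genealogies and 4 cycles with migration free and no high-precision polish
(an order-of-magnitude bound does not need it). These sizes were chosen as the
smallest at which the recovered times resolve the published 95% intervals;
the full-scale schedule above remains the package default for real analyses.

## Numerical choices and degenerate inputs

Zero-probability cells floor at p_min; a model whose parameter draw violates
the event ordering scores −∞ and random starts are re-sorted into a feasible
order; an all-missing site is excluded per pair and logged; a stuck model
(isolated demes with no remaining divergence) raises; exact AIC ties resolve
deterministically; empty matrices yield all-zero spectra. Bootstrap fill
requires at least one observed genotype. The engine caps nothing silently:
buffer overflow in multi-SNP mode grows and retries.

## The dispersal calculator

Seed dispersal distance is modelled as flight speed × gut retention time,
both power laws of body mass (km/h and minutes; the km/h·min → km factor is
exactly 1/60). Coefficients are data, not code: they must be transcribed
from the cited allometric sources into a YAML config with provenance fields,
and a missing block is a configuration error. The bundled config carries
provisional literature-anchored values (retention ∝ m^0.25, speed ∝ m^(1/6))
and the three published target distances for comparison;
`examples/dispersal_validation.py` prints computed vs. published values.

## Known limitations

- Composite likelihood across overlapping pairs: AIC differences are on an
  optimistic scale; model ranking is the supported use.
- Monte-Carlo expected spectra make lnL comparisons noisy below ~1 unit at
  desk scale; increase `n_sims` for fine discrimination.
- No linkage, no genotyping-error model, no ascertainment correction.
- The migration epoch is single and recent by design; ancient-migration
  variants are out of scope.
- Placeholder sizes in the bundled fixtures (see above) until the
  supplementary estimates are transcribed.
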