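"""Composite-likelihood demographic inference on 2D-mSFS data.

The likelihood treats every SFS cell count as an independent multinomial
draw from the model's expected cell probabilities and combines population
pairs by summation of their log-likelihoods (a composite likelihood, since
pairs share sites).  Expected probabilities come from the Monte-Carlo
coalescent engine; cells whose simulated probability is zero are floored at
``min_prob`` (default 1/(10 n_sims)) so a finite simulation never produces
an infinite penalty.

Maximization is expectation-conditional-maximization in the coordinate-ascent
sense used by SFS fitters: cycles of bounded one-dimensional searches (Brent
on log scale) over each free parameter in declaration order, from several
random log-uniform starting points.  Likelihood evaluations share simulation
seeds within a cycle (common random numbers, so conditional moves compare
cleanly) and redraw them across cycles (so the Monte-Carlo realization bias
of any single surface averages out); the final estimate is chosen among the
trailing cycle states of all starts — plus their log-scale means — on one
shared surface, because per-cycle surfaces carry large additive seed noise
that cancels only under common randomness.  ``crn="run"`` instead fixes one
seed per start, giving a deterministic surface and a provably non-decreasing
cycle trace.

Model choice is by Akaike's information criterion, AIC = 2k - 2 lnL (natural
log; base conversion is monotone so selection is unaffected), lowest wins.
Confidence intervals are parametric-bootstrap percentile intervals: simulate
replicate SFS sets at the fitted parameters, refit each starting from the
fit, take the 2.5%/97.5% quantiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import coalsim
from .models import DemographicModel, ModelError, Topology, enumerate_topologies, topology_to_model
from .sfs import SFS2D

__all__ = [
    "FitSchedule",
    "FitResult",
    "BootstrapResult",
    "composite_loglik",
    "ecm_fit",
    "select_best",
    "stepwise_search",
    "parametric_bootstrap",
    "gof_residuals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitSchedule:
    """Optimization budget.

    Defaults are the full-scale protocol (50 starts, 40 ECM cycles, 1e5
    simulations per likelihood evaluation); desk-scale work passes smaller
    numbers.  ``brent_maxiter`` bounds each conditional 1-D search.
    """

    n_starts: int = 50
    n_cycles: int = 40
    n_sims: int = 100_000
    seed: int = 0
    brent_maxiter: int = 10
    min_prob: float | None = None
    include_monomorphic: bool = True
    locus_length: int = coalsim.DEFAULT_LOCUS_LENGTH
    # "cycle": fresh simulation seeds each ECM cycle (shared within the
    # cycle) — Monte-Carlo surface bias averages out across cycles.
    # "run": one seed for the whole start — fully deterministic surface,
    # guaranteed non-decreasing trace.
    crn: str = "cycle"
    # iterate averaging: report the (log-scale) mean of the trailing half of
    # the per-cycle estimates instead of the last cycle alone.  Standard
    # variance reduction for stochastic coordinate ascent; only active with
    # per-cycle common random numbers.
    polyak: bool = True
    # coarse-to-fine polish: score the candidate pool, and run one final
    # conditional-maximization pass over the winner, on a single surface
    # with `refine_factor` times the per-cycle simulation count.  Resolves
    # likelihood ridges whose depth is below the per-cycle noise.
    refine: bool = True
    refine_factor: int = 4

    def __post_init__(self) -> None:
        if min(self.n_starts, self.n_cycles, self.n_sims) < 1:
            raise ModelError("schedule counts must be positive")

    @property
    def floor(self) -> float:
        return self.min_prob if self.min_prob is not None else 1.0 / (10.0 * self.n_sims)


@dataclass
class FitResult:
    model_id: str
    params: dict[str, float]
    lnL: float
    k: int
    AIC: float
    trace: list[float]
    converged: bool
    n_evals: int = 0

    @classmethod
    def make(cls, model_id, params, lnL, k, trace, converged, n_evals=0):
        return cls(
            model_id=model_id,
            params=dict(params),
            lnL=float(lnL),
            k=int(k),
            AIC=2.0 * k - 2.0 * lnL,
            trace=list(trace),
            converged=bool(converged),
            n_evals=int(n_evals),
        )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "lnL": self.lnL,
            "k": self.k,
            "AIC": self.AIC,
            "trace": self.trace,
            "converged": self.converged,
        }


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame
    ci: dict[str, tuple[float, float]]
    n_failed: int = 0


# ---------------------------------------------------------------------------
# likelihood


def composite_loglik(
    obs: Sequence[SFS2D] | SFS2D,
    expected: Sequence[np.ndarray] | np.ndarray,
    min_prob: float = 1e-6,
    *,
    include_monomorphic: bool = True,
) -> float:
    """Natural-log composite likelihood of one or more observed 2D-mSFS.

    lnL = sum over pairs, sum over cells of count * ln(max(p, min_prob)).
    With ``include_monomorphic=False`` the (0, 0) cell is dropped and the
    expected table renormalized over polymorphic cells.
    """
    if isinstance(obs, SFS2D):
        obs = [obs]
        expected = [expected]
    if len(obs) != len(expected):
        raise ModelError("obs and expected lists differ in length")
    lnL = 0.0
    for o, p in zip(obs, expected):
        p = np.asarray(p, dtype=float)
        if o.counts.shape != p.shape:
            raise ModelError(
                f"shape mismatch for pair {o.pair}: {o.counts.shape} vs {p.shape}"
            )
        c = o.counts
        if not include_monomorphic:
            denom = 1.0 - p[0, 0]
            p = p / max(denom, min_prob)
            mask = np.ones_like(p, dtype=bool)
            mask[0, 0] = False
            lnL += float(np.sum(c[mask] * np.log(np.maximum(p[mask], min_prob))))
        else:
            lnL += float(np.sum(c * np.log(np.maximum(p, min_prob))))
    return lnL


class _Objective:
    """Cached composite likelihood of a model over fixed pairs under CRN."""

    def __init__(self, model, obs, pairs, schedule, crn_seed):
        self.model = model
        self.obs = obs
        self.pairs = pairs
        self.schedule = schedule
        self.crn_seed = crn_seed
        self.cache: dict[tuple, float] = {}
        self.n_evals = 0

    def __call__(self, values: Mapping[str, float]) -> float:
        key = tuple(sorted((k, round(float(v), 10)) for k, v in values.items()))
        if key in self.cache:
            return self.cache[key]
        try:
            m = self.model.with_params(values)
        except ModelError:
            self.cache[key] = -np.inf
            return -np.inf
        exp = coalsim.expected_sfs_pairs(
            m,
            self.pairs,
            n_sims=self.schedule.n_sims,
            seed=self.crn_seed,
            locus_length=self.schedule.locus_length,
        )
        lnL = composite_loglik(
            [self.obs[p] for p in self.pairs],
            [exp[p] for p in self.pairs],
            self.schedule.floor,
            include_monomorphic=self.schedule.include_monomorphic,
        )
        self.n_evals += 1
        self.cache[key] = lnL
        return lnL


def _normalize_obs(obs: Mapping[tuple[str, str], SFS2D]) -> dict:
    return {tuple(k): v for k, v in obs.items()}


def ecm_fit(
    model: DemographicModel,
    obs: Mapping[tuple[str, str], SFS2D],
    schedule: FitSchedule,
    *,
    start_values: Sequence[Mapping[str, float]] | None = None,
) -> FitResult:
    """Fit the model's free parameters to observed pairwise 2D-mSFS.

    Starting points are log-uniform draws within each parameter's bounds
    (or the explicit ``start_values``, recycled over starts).  Each start runs
    ``n_cycles`` coordinate-ascent cycles; within a cycle each parameter is
    maximized by a bounded Brent search on its (log) scale, restricted to the
    interval where the event ordering stays feasible given the other
    parameters.  A proposal is only accepted if it improves the cached
    common-random-number likelihood, so the cycle trace is non-decreasing.
    The best start wins.
    """
    obs = _normalize_obs(obs)
    pairs = list(obs.keys())
    free = model.free_params
    if not free:
        objective = _Objective(model, obs, pairs, schedule, _derive_seed(schedule.seed, 0))
        lnL = objective({})
        return FitResult.make(model.name, {}, lnL, 0, [lnL], np.isfinite(lnL),
                              objective.n_evals)

    rng = np.random.default_rng([int(schedule.seed) % (2**31), 1])
    best: FitResult | None = None
    candidates: list[tuple[dict[str, float], list[float], int]] = []
    for s in range(schedule.n_starts):
        crn_seed = _derive_seed(schedule.seed, s)
        objective = _Objective(model, obs, pairs, schedule, crn_seed)
        if start_values is not None:
            values = dict(start_values[s % len(start_values)])
        else:
            values = {}
            for par in free:
                lo, hi = par.bounds
                if par.log_scale:
                    values[par.name] = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
                else:
                    values[par.name] = rng.uniform(lo, hi)
            # random starts may violate the event ordering; nudge times into a
            # feasible configuration by sorting draws onto the events' order
            values = _feasible_start(model, values, rng)
        lnL = objective(values)
        trace: list[float] = []
        history: list[dict[str, float]] = []
        n_evals = 0
        for cycle in range(schedule.n_cycles):
            if schedule.crn == "cycle" and cycle > 0:
                # fresh common random numbers for this cycle
                n_evals += objective.n_evals
                objective = _Objective(
                    model, obs, pairs, schedule,
                    _derive_seed(schedule.seed, s * 997 + cycle),
                )
                lnL = objective(values)
            for par in free:
                current = model.with_params(values)
                lo, hi = par.bounds
                if all(sl["kind"] == "event_time" for sl in par.slots):
                    blo, bhi = current.time_bracket(par.name)
                    lo, hi = max(lo, blo), min(hi, bhi)
                if not lo < hi:
                    continue
                x_new, f_new, _ = _line_search(
                    objective, values, par, lo, hi, schedule.brent_maxiter
                )
                if f_new > lnL:
                    values[par.name] = x_new
                    lnL = f_new
            trace.append(lnL)
            history.append(dict(values))
        if schedule.crn == "run":
            result = FitResult.make(
                model.name, values, lnL, len(free), trace,
                np.isfinite(lnL), n_evals + objective.n_evals,
            )
            if best is None or result.lnL > best.lnL:
                best = result
            continue
        if not np.isfinite(lnL):
            continue
        # candidate pool for the shared-surface selection below: the
        # trailing-half cycle states and (optionally) their log-scale mean
        tail = history[len(history) // 2:]
        for h in tail:
            candidates.append((h, trace, n_evals + objective.n_evals))
        if schedule.polyak and schedule.n_cycles >= 4:
            avg: dict[str, float] = {}
            for par in free:
                xs = np.array([h[par.name] for h in tail])
                avg[par.name] = (
                    float(10 ** np.mean(np.log10(xs)))
                    if par.log_scale
                    else float(np.mean(xs))
                )
            # pairwise order constraints hold in every cycle, hence under
            # the (log-)mean as well; infeasible averages score -inf below
            candidates.append((avg, trace, n_evals + objective.n_evals))

    if schedule.crn != "run":
        if not candidates:
            raise ModelError("all starting points yielded non-finite likelihood")
        # per-cycle surfaces carry large seed-to-seed offsets, so configs
        # from different starts/cycles cannot be compared on their own
        # surfaces; one shared common-random-number surface (at a higher
        # simulation count, when refinement is on) makes the comparison
        # noise-free to within the CRN residual
        sel_schedule = (
            replace(schedule, n_sims=schedule.n_sims * schedule.refine_factor)
            if schedule.refine
            else schedule
        )
        selector = _Objective(
            model, obs, pairs, sel_schedule, _derive_seed(schedule.seed, 999_983)
        )
        scored = [(selector(vals), i) for i, (vals, _, _) in enumerate(candidates)]
        f_best, i_best = max(scored)
        vals, trace, ne = candidates[i_best]
        vals = dict(vals)
        if schedule.refine and np.isfinite(f_best):
            # one conditional-maximization pass over the winner on the
            # high-precision surface
            for par in free:
                current = model.with_params(vals)
                lo, hi = par.bounds
                if all(sl["kind"] == "event_time" for sl in par.slots):
                    blo, bhi = current.time_bracket(par.name)
                    lo, hi = max(lo, blo), min(hi, bhi)
                if not lo < hi:
                    continue
                x_new, f_new, _ = _line_search(
                    selector, vals, par, lo, hi, schedule.brent_maxiter
                )
                if f_new > f_best:
                    vals[par.name] = x_new
                    f_best = f_new
        best = FitResult.make(
            model.name, vals, f_best, len(free), trace,
            np.isfinite(f_best), ne + selector.n_evals,
        )
    if best is None or not np.isfinite(best.lnL):
        raise ModelError("all starting points yielded non-finite likelihood")
    return best


def _derive_seed(seed: int, start: int) -> int:
    return int((int(seed) * 7919 + start * 104729 + 13)) % 2147483647


def _feasible_start(model, values, rng, max_tries: int = 50):
    if model.is_feasible(values):
        return values
    time_params = [
        p.name for p in model.free_params
        if all(sl["kind"] == "event_time" for sl in p.slots)
    ]
    ref = model.param_values()
    order = sorted(time_params, key=lambda n: ref[n])
    for _ in range(max_tries):
        draws = sorted(values[n] for n in time_params)
        cand = dict(values)
        for name, v in zip(order, draws):
            cand[name] = v
        if model.is_feasible(cand):
            return cand
        for p in model.free_params:
            if p.name in time_params:
                lo, hi = p.bounds
                values[p.name] = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
    # fall back to the model's own (valid) configuration
    return {n: ref[n] for n in values}


def _line_search(objective, values, par, lo, hi, maxiter):
    """Bounded Brent maximization of one parameter; returns (x, f, n)."""
    log = par.log_scale

    def neg(x):
        v = dict(values)
        v[par.name] = 10 ** x if log else x
        return -objective(v)

    a, b = (math.log10(lo), math.log10(hi)) if log else (lo, hi)
    res = minimize_scalar(
        neg, bounds=(a, b), method="bounded",
        options={"maxiter": maxiter, "xatol": (b - a) * 1e-3},
    )
    x = 10 ** res.x if log else float(res.x)
    return x, -res.fun, res.nfev


# ---------------------------------------------------------------------------
# model selection


def select_best(fits: Sequence[FitResult]) -> tuple[FitResult, pd.DataFrame]:
    """Lowest-AIC fit plus a ΔAIC table.

    Ties prefer fewer parameters, then lexicographic model id (documented
    deterministic tie rule)."""
    if not fits:
        raise ModelError("select_best needs at least one fit")
    ranked = sorted(fits, key=lambda f: (f.AIC, f.k, f.model_id))
    best = ranked[0]
    table = pd.DataFrame(
        {
            "model_id": [f.model_id for f in ranked],
            "k": [f.k for f in ranked],
            "lnL": [f.lnL for f in ranked],
            "AIC": [f.AIC for f in ranked],
            "dAIC": [f.AIC - best.AIC for f in ranked],
        }
    )
    return best, table


def stepwise_search(
    step_plan: Sequence[Sequence[str]],
    data: Mapping[tuple[str, str], SFS2D],
    populations,
    schedule: FitSchedule,
    *,
    mu: float = 1.74e-8,
) -> dict:
    """The sequential model-building ladder: at each step enumerate candidate
    divergence orderings of that step's taxa, constrained by the clades the
    previous steps' winners established, fit them all and keep the lowest
    AIC.  Returns a machine-readable path (per-step winner + ΔAIC table) and
    the final winning model and fit."""
    data = _normalize_obs(data)
    taxa_in_data = {t for pair in data for t in pair}
    path = []
    won_clades: set[frozenset] = set()
    final = None
    for step_i, taxa in enumerate(step_plan):
        missing = set(taxa) - taxa_in_data
        if missing:
            raise ModelError(f"step {step_i}: taxa absent from data: {sorted(missing)}")
        constraints = [c for c in won_clades if c < set(taxa) and len(c) > 1]
        topos = enumerate_topologies(taxa, constraints)
        step_pairs = [
            p for p in data
            if p[0] in taxa and p[1] in taxa
        ]
        step_obs = {p: data[p] for p in step_pairs}
        fits = []
        by_id: dict[str, Topology] = {}
        for topo in topos:
            m = topology_to_model(topo, populations, mu=mu)
            by_id[m.name] = topo
            fits.append(ecm_fit(m, step_obs, schedule))
        best, table = select_best(fits)
        won_clades |= by_id[best.model_id].clades()
        path.append({"step": step_i, "taxa": list(taxa), "winner": best.model_id,
                     "table": table, "fit": best})
        final = (topology_to_model(by_id[best.model_id], populations, mu=mu), best)
    return {"path": path, "best_model": final[0], "best_fit": final[1]}


# ---------------------------------------------------------------------------
# parametric bootstrap


def parametric_bootstrap(
    best: FitResult,
    model: DemographicModel,
    schedule_boot: FitSchedule,
    n_reps: int = 100,
    *,
    n_sites: int | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    sfs_seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap CIs: simulate ``n_reps`` datasets at the fitted
    parameters, refit each starting from the fit, take 2.5/97.5 quantiles.

    Replicate refits that fail are logged and dropped, never fatal.
    """
    if not best.converged:
        raise ModelError("parametric_bootstrap requires a converged fit")
    if not model.free_params:
        return BootstrapResult(pd.DataFrame(), {}, 0)
    from .sfs import build_2d_msfs  # local import to avoid cycle at import time

    fitted = model.with_params(best.params)
    if pairs is None:
        names = fitted.pop_names
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    if n_sites is None:
        raise ModelError("n_sites (sites per replicate dataset) is required")
    rows = []
    n_failed = 0
    boot = replace(schedule_boot, n_starts=1)
    for rep in range(n_reps):
        rep_seed = _derive_seed(sfs_seed, 1000 + rep)
        g = coalsim.simulate_genotypes(
            fitted, n_sites, seed=rep_seed, locus_length=schedule_boot.locus_length
        )
        obs = {p: build_2d_msfs(g, *p, seed=rep_seed) for p in pairs}
        try:
            fit = ecm_fit(
                fitted, obs, replace(boot, seed=rep_seed),
                start_values=[best.params],
            )
            rows.append(fit.params)
        except ModelError as exc:  # pragma: no cover - rare refit failure
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            n_failed += 1
    reps = pd.DataFrame(rows)
    ci = {
        name: (
            float(np.percentile(reps[name], 2.5)),
            float(np.percentile(reps[name], 97.5)),
        )
        for name in reps.columns
    }
    return BootstrapResult(replicates=reps, ci=ci, n_failed=n_failed)


# ---------------------------------------------------------------------------
# goodness of fit


def gof_residuals(
    obs: SFS2D,
    fitted_expected: np.ndarray,
    *,
    heatmap_path=None,
):
    """Per-cell Pearson residuals (obs - E)/sqrt(E), E = total * p, plus the
    residual sum of squares; optionally renders observed/expected heatmaps."""
    p = np.asarray(fitted_expected, dtype=float)
    if obs.counts.shape != p.shape:
        raise ModelError("gof_residuals: shape mismatch")
    E = obs.total * p
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.where(E > 0, (obs.counts - E) / np.sqrt(np.where(E > 0, E, 1.0)), 0.0)
        resid = np.where((E <= 0) & (obs.counts > 0), np.inf, resid)
    finite = np.isfinite(resid)
    aggregate = float(np.sum(resid[finite] ** 2))
    if heatmap_path is not None:
        _render_gof(obs, E, resid, heatmap_path)
    return resid, aggregate


def _render_gof(obs, E, resid, path):  # pragma: no cover - plotting side output
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (mat, title) in zip(
        axes,
        [(np.log1p(obs.counts), "observed (log1p)"),
         (np.log1p(E), "expected (log1p)"),
         (resid, "Pearson residuals")],
    ):
        im = ax.imshow(mat, origin="lower", aspect="auto")
        ax.set_title(title)
        ax.set_xlabel(obs.pair[1])
        ax.set_ylabel(obs.pair[0])
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
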