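"""Self-consistency parameter-recovery experiments on the best models.

The real genotype deposition is not required: data are simulated under the
catalog models with the published point estimates as truth, the free
parameters are refit with a desk-scale ECM schedule, and the recovered values
are compared with the published estimates/intervals.  Because the truth is
set to the published point estimate, successful recovery demonstrates that
the whole pipeline (simulation -> 2D-mSFS -> composite likelihood -> ECM) is
internally consistent at the study's sampling design.

Desk-scale problem sizes (the package's defaults for these experiments):
50,000 unlinked RAD loci of observed data, 5,000 simulated genealogies per
likelihood evaluation, 3 random starts, 10 ECM cycles.  The migration-bound
experiment uses 10 seeded runs at a lighter schedule (20,000 loci, 2,500
genealogies, 4 cycles) since it checks an order-of-magnitude bound rather
than a point estimate.
"""

from __future__ import annotations

import numpy as np

from . import catalog, coalsim
from .fit import FitSchedule, ecm_fit
from .models import TimeScale, generations_to_years
from .sfs import build_2d_msfs

__all__ = [
    "recovery_e1",
    "recovery_g2",
    "migration_bound",
    "MIGRANT_RANGE",
]

# published range of migrant numbers per generation in the best models
MIGRANT_RANGE = (0.020, 0.511)

_TS = TimeScale(5.0)


def _kya(t_gen: float) -> float:
    return generations_to_years(t_gen, _TS) / 1000.0


def _all_pairs(model):
    names = model.pop_names
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]


def _seed(base: int, salt: int) -> int:
    return int(base * 9973 + salt) % 2147483647


def _recover_times(model, free_names, seed, n_sites, n_sims, n_starts, n_cycles):
    """Simulate data at the model's truth, refit the named time parameters
    (everything else fixed at truth), return the fit."""
    m_fit = model.restrict(free_names)
    g = coalsim.simulate_genotypes(model, n_sites, seed=_seed(seed, 1))
    pairs = _all_pairs(model)
    obs = {p: build_2d_msfs(g, *p, seed=_seed(seed, 2)) for p in pairs}
    sched = FitSchedule(
        n_starts=n_starts, n_cycles=n_cycles, n_sims=n_sims, seed=_seed(seed, 3)
    )
    return ecm_fit(m_fit, obs, sched), g.n_sites


def recovery_e1(
    seed: int = 1,
    *,
    n_sites: int = 50_000,
    n_sims: int = 5_000,
    n_starts: int = 3,
    n_cycles: int = 10,
) -> dict:
    """Six-deme recovery under model e1, divergence times free.

    Returns the refitted divergence times in kya (5 yr/generation); the
    headline quantity is the oldest split (ecotype ST vs the rest).
    """
    model = catalog.model_e1()
    fit, n = _recover_times(
        model, ["T1", "T2", "T3", "T4", "T5"], seed, n_sites, n_sims,
        n_starts, n_cycles,
    )
    truth = model.param_values()
    return {
        "t_oldest_kya": _kya(fit.params["T1"]),
        "times_kya": {k: _kya(v) for k, v in fit.params.items()},
        "truth_kya": {k: _kya(truth[k]) for k in fit.params},
        "lnL": fit.lnL,
        "n_sites": n,
    }


def recovery_g2(
    seed: int = 1,
    *,
    n_sites: int = 50_000,
    n_sims: int = 5_000,
    n_starts: int = 3,
    n_cycles: int = 10,
) -> dict:
    """Five-deme recovery under model g2: Mukojima founding splits, the
    ancestral-lineage split, and the shared reduction time, all free."""
    model = catalog.model_g2()
    fit, n = _recover_times(
        model, ["T1", "T2", "T3", "TSG", "Tred"], seed, n_sites, n_sims,
        n_starts, n_cycles,
    )
    truth = model.param_values()
    return {
        "t_sm_split_kya": _kya(fit.params["T2"]),
        "t_stm_split_kya": _kya(fit.params["T3"]),
        "t_ancestral_kya": _kya(fit.params["T1"]),
        "t_reduction_kya": _kya(fit.params["Tred"]),
        "times_kya": {k: _kya(v) for k, v in fit.params.items()},
        "truth_kya": {k: _kya(truth[k]) for k in fit.params},
        "lnL": fit.lnL,
        "n_sites": n,
    }


def migration_bound(
    seed: int = 1,
    *,
    n_runs: int = 10,
    n_sites: int = 20_000,
    n_sims: int = 2_500,
    n_cycles: int = 4,
) -> dict:
    """Seeded e1/g2 recovery runs with migration free.

    True migrant numbers per generation are drawn uniformly inside the
    published range for every within-island-group pair; the refitted migrant
    numbers (forward fraction x destination deme size during the migration
    epoch) are collected across all pairs and runs.  The headline quantity is
    their maximum, which the published estimates bound by 1.0.
    """
    lo, hi = MIGRANT_RANGE
    all_migrants: list[float] = []
    per_run = []
    for run in range(n_runs):
        model = catalog.model_e1() if run % 2 == 0 else catalog.model_g2()
        rng = np.random.default_rng([seed, run])
        mig_params = [p for p in model.free_params if p.slots[0]["kind"] == "migration"]
        dest_n = {}
        truths = {}
        for par in mig_params:
            dest = par.slots[0]["to"]
            N_dest = model.population(dest).N_current
            m_true = rng.uniform(lo, hi) / N_dest
            truths[par.name] = m_true
            dest_n[par.name] = N_dest
        model = model.with_params(truths)
        m_fit = model.restrict(truths.keys())
        g = coalsim.simulate_genotypes(model, n_sites, seed=_seed(seed, 100 + run))
        pairs = _all_pairs(model)
        obs = {p: build_2d_msfs(g, *p, seed=_seed(seed, 200 + run)) for p in pairs}
        # an order-of-magnitude bound needs no high-precision polish
        sched = FitSchedule(
            n_starts=1, n_cycles=n_cycles, n_sims=n_sims,
            seed=_seed(seed, 300 + run), refine=False,
        )
        fit = ecm_fit(m_fit, obs, sched)
        migrants = {k: fit.params[k] * dest_n[k] for k in fit.params}
        all_migrants.extend(migrants.values())
        per_run.append(
            {
                "model": model.name,
                "migrants_true": {k: truths[k] * dest_n[k] for k in truths},
                "migrants_fit": migrants,
            }
        )
    return {
        "max_migrants_per_generation": float(max(all_migrants)),
        "runs": per_run,
        "n_runs": n_runs,
        "n_sites": n_sites,
    }
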