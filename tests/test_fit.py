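"""Composite likelihood, ECM optimization, model selection, bootstrap, GOF."""

import numpy as np
import pytest

from demosfs import coalsim
from demosfs.fit import (
    FitResult,
    FitSchedule,
    composite_loglik,
    ecm_fit,
    gof_residuals,
    parametric_bootstrap,
    select_best,
    stepwise_search,
)
from demosfs.models import ModelError, Population
from demosfs.sfs import SFS2D, build_2d_msfs

from conftest import make_two_deme


def _sfs(counts, pair=("A", "B")):
    counts = np.asarray(counts, dtype=float)
    return SFS2D(pair, counts.shape[0] - 1, counts.shape[1] - 1, counts)


class TestCompositeLoglik:
    def test_closed_form(self):
        obs = _sfs([[2.0, 2.0], [0.0, 0.0]])
        p = np.array([[0.5, 0.5], [0.0, 0.0]])
        assert composite_loglik(obs, p, 1e-9) == pytest.approx(4 * np.log(0.5))

    def test_gibbs_inequality(self):
        rng = np.random.default_rng(0)
        counts = np.array([[30.0, 12.0], [8.0, 0.0]])
        obs = _sfs(counts)
        p_hat = counts / counts.sum()
        best = composite_loglik(obs, p_hat, 1e-12)
        for _ in range(500):
            q = rng.dirichlet(np.ones(3))
            qtab = np.array([[q[0], q[1]], [q[2], 0.0]])
            assert composite_loglik(obs, qtab, 1e-12) <= best + 1e-9

    def test_min_prob_substitution(self):
        # count 3 on a zero-probability cell contributes 3 ln(1e-8), finite
        obs = _sfs([[1.0, 3.0], [0.0, 0.0]])
        p = np.array([[1.0, 0.0], [0.0, 0.0]])
        lnL = composite_loglik(obs, p, 1e-8)
        assert np.isfinite(lnL)
        assert lnL == pytest.approx(3 * np.log(1e-8))

    def test_shape_mismatch_rejected(self):
        obs = _sfs([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ModelError):
            composite_loglik(obs, np.ones((3, 3)) / 9)

    def test_polymorphic_only_mode(self):
        obs = _sfs([[100.0, 10.0], [5.0, 0.0]])
        p = np.array([[0.8, 0.1], [0.1, 0.0]])
        lnL = composite_loglik(obs, p, 1e-9, include_monomorphic=False)
        # monomorphic count ignored; conditional probabilities renormalized
        assert lnL == pytest.approx(10 * np.log(0.5) + 5 * np.log(0.5))


class TestSelection:
    def test_aic_formula(self):
        f = FitResult.make("m", {}, -100.0, 5, [], True)
        assert f.AIC == 210.0

    def test_argmin_and_delta(self):
        f1 = FitResult.make("m1", {}, -100.0, 5, [], True)  # AIC 210
        f2 = FitResult.make("m2", {}, -100.0, 7.5, [], True)  # AIC 215
        best, table = select_best([f1, f2])
        assert best is f1
        assert table["dAIC"].tolist() == [0.0, 5.0]

    def test_tie_rules(self):
        a = FitResult.make("b_model", {}, -100.0, 5, [], True)
        b = FitResult.make("a_model", {}, -99.0, 6, [], True)  # same AIC, more k
        best, _ = select_best([a, b])
        assert best is a  # fewer parameters win the tie
        c = FitResult.make("a_model", {}, -100.0, 5, [], True)
        best2, _ = select_best([a, c])
        assert best2.model_id == "a_model"  # lexicographic at equal k

    def test_empty_rejected(self):
        with pytest.raises(ModelError):
            select_best([])

    def test_order_invariant(self):
        fits = [
            FitResult.make(f"m{i}", {}, -100.0 - i, 3, [], True) for i in range(4)
        ]
        b1, _ = select_best(fits)
        b2, _ = select_best(fits[::-1])
        assert b1.model_id == b2.model_id


@pytest.fixture(scope="module")
def two_deme_obs():
    m = make_two_deme(t_split=2000.0)
    g = coalsim.simulate_genotypes(m, 20_000, seed=11)
    return m, {("A", "B"): build_2d_msfs(g, "A", "B", seed=1)}


class TestECM:
    def test_deterministic(self, two_deme_obs):
        m, obs = two_deme_obs
        sched = FitSchedule(n_starts=2, n_cycles=3, n_sims=1500, seed=9)
        f1 = ecm_fit(m, obs, sched)
        f2 = ecm_fit(m, obs, sched)
        assert f1.params == f2.params and f1.lnL == f2.lnL

    def test_trace_monotone_under_crn(self, two_deme_obs):
        m, obs = two_deme_obs
        f = ecm_fit(
            m, obs,
            FitSchedule(n_starts=1, n_cycles=6, n_sims=1500, seed=4, crn="run"),
        )
        assert all(b >= a - 1e-9 for a, b in zip(f.trace, f.trace[1:]))
        assert f.AIC == pytest.approx(2 * f.k - 2 * f.lnL)

    def test_divergence_time_recovery(self):
        # truth T = 2000 generations, size fixed at truth: the refit lands
        # within 15% of truth in at least 9 of 10 seeded runs
        hits = 0
        for seed in range(10):
            m = make_two_deme(t_split=2000.0)
            g = coalsim.simulate_genotypes(m, 8000, seed=100 + seed)
            obs = {("A", "B"): build_2d_msfs(g, "A", "B", seed=seed)}
            sched = FitSchedule(n_starts=3, n_cycles=8, n_sims=3000, seed=seed)
            f = ecm_fit(m, obs, sched)
            if abs(f.params["T"] - 2000.0) / 2000.0 < 0.15:
                hits += 1
        assert hits >= 9

    def test_no_free_parameters_evaluation_only(self, two_deme_obs):
        m, obs = two_deme_obs
        f = ecm_fit(
            m.restrict([]), obs, FitSchedule(n_starts=1, n_cycles=1, n_sims=1000, seed=2)
        )
        assert f.k == 0 and f.params == {} and np.isfinite(f.lnL)


class TestStepwise:
    def test_topology_selection_power(self):
        # data simulated under a strictly ordered 3-taxon history: the true
        # ordering wins the AIC race in >= 8/10 seeded runs at desk scale
        from demosfs.models import DemographicEvent, DemographicModel, FreeParameter

        pops = tuple(Population(n, "X", 3, 2000) for n in "ABC")
        truth = DemographicModel(
            pops,
            (
                DemographicEvent(1500, "divergence", "B", "A"),
                DemographicEvent(6000, "divergence", "C", "A"),
            ),
        )
        wins = 0
        for seed in range(10):
            g = coalsim.simulate_genotypes(truth, 12_000, seed=500 + seed)
            data = {
                p: build_2d_msfs(g, *p, seed=seed)
                for p in [("A", "B"), ("A", "C"), ("B", "C")]
            }
            sched = FitSchedule(n_starts=1, n_cycles=4, n_sims=2000, seed=seed)
            res = stepwise_search([["A", "B", "C"]], data, pops, sched)
            if res["best_fit"].model_id == "((A,B),C)":
                wins += 1
        assert wins >= 8

    def test_single_candidate_step(self):
        pops = tuple(Population(n, "X", 2, 2000) for n in "AB")
        truth = make_two_deme(t_split=2000.0, n_dip=2)
        g = coalsim.simulate_genotypes(truth, 2000, seed=3)
        data = {("A", "B"): build_2d_msfs(g, "A", "B", seed=0)}
        sched = FitSchedule(n_starts=1, n_cycles=2, n_sims=1000, seed=1)
        res = stepwise_search([["A", "B"]], data, pops, sched)
        assert len(res["path"]) == 1
        assert len(res["path"][0]["table"]) == 1

    def test_unknown_taxon_rejected(self):
        pops = tuple(Population(n, "X", 2, 2000) for n in "AB")
        with pytest.raises(ModelError):
            stepwise_search(
                [["A", "Z"]], {("A", "B"): _sfs(np.zeros((5, 5)))}, pops,
                FitSchedule(n_starts=1, n_cycles=1, n_sims=10, seed=0),
            )


class TestBootstrap:
    def test_replicate_table_and_ci(self):
        m = make_two_deme(t_split=2000.0, n_dip=3)
        g = coalsim.simulate_genotypes(m, 4000, seed=42)
        obs = {("A", "B"): build_2d_msfs(g, "A", "B", seed=0)}
        sched = FitSchedule(n_starts=2, n_cycles=4, n_sims=1500, seed=7)
        best = ecm_fit(m, obs, sched)
        boot = parametric_bootstrap(
            best, m, FitSchedule(n_starts=1, n_cycles=3, n_sims=1500, seed=7),
            n_reps=8, n_sites=4000, sfs_seed=3,
        )
        assert len(boot.replicates) <= 8
        lo, hi = boot.ci["T"]
        assert lo <= hi

    def test_ci_coverage_on_two_deme_toy(self):
        # percentile bootstrap CI covers the data-generating divergence time
        # in ~95% of repetitions (binomial slack at 20 outer repetitions:
        # P(<15 hits | p=0.95) < 3e-4)
        hits = 0
        n_outer = 20
        for rep in range(n_outer):
            m = make_two_deme(t_split=2000.0, n_dip=3)
            g = coalsim.simulate_genotypes(m, 3000, seed=7000 + rep)
            obs = {("A", "B"): build_2d_msfs(g, "A", "B", seed=rep)}
            sched = FitSchedule(n_starts=2, n_cycles=4, n_sims=1500, seed=rep)
            best = ecm_fit(m, obs, sched)
            boot = parametric_bootstrap(
                best, m,
                FitSchedule(n_starts=1, n_cycles=3, n_sims=1200, seed=rep),
                n_reps=24, n_sites=3000, sfs_seed=rep,
            )
            lo, hi = boot.ci["T"]
            hits += int(lo <= 2000.0 <= hi)
        assert hits >= 15

    def test_degenerate_no_free_parameters(self):
        m = make_two_deme(free_time=False)
        best = FitResult.make("m", {}, -10.0, 0, [], True)
        boot = parametric_bootstrap(
            best, m, FitSchedule(n_starts=1, n_cycles=1, n_sims=100, seed=0),
            n_reps=5, n_sites=100,
        )
        assert boot.ci == {} and boot.replicates.empty


class TestGOF:
    def test_exact_fit_gives_zero_residuals(self):
        p = np.array([[0.5, 0.25], [0.25, 0.0]])
        obs = _sfs(400 * p)
        resid, rss = gof_residuals(obs, p)
        assert np.allclose(resid, 0.0) and rss == 0.0

    def test_single_cell_excess(self):
        p = np.array([[0.5, 0.25], [0.25, 0.0]])
        counts = 400 * p
        counts[0, 1] += 10.0  # +k over expectation E
        obs = _sfs(counts)
        total = obs.total
        E01 = total * 0.25
        resid, _ = gof_residuals(obs, p)
        assert resid[0, 1] == pytest.approx((counts[0, 1] - E01) / np.sqrt(E01))

    def test_null_calibration(self):
        # data simulated from the fitted model: the aggregate statistic falls
        # inside the central 99% of its own simulated null distribution
        m = make_two_deme(t_split=2000.0, n_dip=3, free_time=False)
        p = coalsim.expected_sfs(m, ("A", "B"), n_sims=50_000, seed=77)
        g = coalsim.simulate_genotypes(m, 5000, seed=13)
        obs = build_2d_msfs(g, "A", "B", seed=0)
        _, rss_obs = gof_residuals(obs, p)
        rng = np.random.default_rng(5)
        null = []
        for _ in range(200):
            draw = rng.multinomial(int(obs.total), p.ravel()).reshape(p.shape)
            _, rss = gof_residuals(_sfs(draw), p)
            null.append(rss)
        lo, hi = np.percentile(null, [0.5, 99.5])
        assert lo <= rss_obs <= hi
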