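"""Domain types, time conversion, config construction, candidate enumeration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demosfs import catalog
from demosfs.models import (
    DemographicEvent,
    DemographicModel,
    MigrationEpoch,
    ModelError,
    Population,
    TimeScale,
    build_model,
    enumerate_candidates,
    enumerate_topologies,
    generations_to_years,
    years_to_generations,
)


class TestTimeScale:
    def test_oldest_split_converts_to_published_age(self):
        # 34,140 generations at 5 yr/gen = 170,700 years (the ST split)
        assert generations_to_years(34_140, TimeScale(5.0)) == pytest.approx(170_700)

    def test_zero_is_zero(self):
        assert generations_to_years(0.0) == 0.0

    @given(st.floats(min_value=0, max_value=1e8, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, t):
        ts = TimeScale(5.0)
        assert years_to_generations(generations_to_years(t, ts), ts) == pytest.approx(t)

    @given(
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_conversion_commutes_with_scaling(self, t, k):
        assert generations_to_years(k * t) == pytest.approx(k * generations_to_years(t))

    def test_negative_time_rejected(self):
        with pytest.raises(ModelError):
            generations_to_years(-1.0)
        with pytest.raises(ModelError):
            TimeScale(0.0)


class TestInvariants:
    def test_population_validation(self):
        with pytest.raises(ModelError):
            Population("A", "X", 0, 100)
        with pytest.raises(ModelError):
            Population("A", "X", 1, 0)
        with pytest.raises(ModelError):
            Population("A", "", 1, 100)

    def test_divergence_needs_distinct_demes(self):
        with pytest.raises(ModelError):
            DemographicEvent(10, "divergence", "A", "A")
        with pytest.raises(ModelError):
            DemographicEvent(-1, "divergence", "A", "B")

    def test_migration_fraction_bounds(self):
        with pytest.raises(ModelError):
            MigrationEpoch(100, {("A", "B"): 1.5})

    def test_cross_island_group_migration_rejected(self):
        pops = (Population("A", "X", 2, 100), Population("B", "Y", 2, 100))
        ev = (DemographicEvent(50, "divergence", "B", "A"),)
        with pytest.raises(ModelError, match="island"):
            DemographicModel(pops, ev, MigrationEpoch(10, {("A", "B"): 1e-4}))

    def test_merged_deme_cannot_diverge_again(self):
        pops = (
            Population("A", "X", 2, 100),
            Population("B", "X", 2, 100),
            Population("C", "X", 2, 100),
        )
        # B merges into A at t=10, then "B" splits from C at an older time:
        # B is already gone looking backward -> topology error
        ev = (
            DemographicEvent(10, "divergence", "B", "A"),
            DemographicEvent(50, "divergence", "B", "C"),
        )
        with pytest.raises(ModelError, match="already merged"):
            DemographicModel(pops, ev)

    def test_lineage_count_must_reach_one(self):
        pops = (Population("A", "X", 2, 100), Population("B", "X", 2, 100))
        with pytest.raises(ModelError, match="ancestral"):
            DemographicModel(pops, ())  # two demes, no divergence


class TestBuildModel:
    def test_bundled_e1_has_five_divergences_and_legal_migration(self):
        m = catalog.model_e1()
        div = [e for e in m.events if e.kind == "divergence"]
        assert len(div) == 5
        groups = {p.name: p.island_group for p in m.populations}
        for (i, j) in m.migration.rates:
            assert groups[i] == groups[j]

    def test_single_population_spec(self):
        m = build_model(
            {"populations": [{"name": "A", "island_group": "X", "N_current": 100}]}
        )
        assert len(m.events) == 0 and len(m.populations) == 1

    def test_child_older_than_parent_rejected(self):
        spec = {
            "populations": [
                {"name": "A", "island_group": "X", "N_current": 100},
                {"name": "B", "island_group": "X", "N_current": 100},
                {"name": "C", "island_group": "X", "N_current": 100},
            ],
            "events": [
                {"time": 500, "kind": "divergence", "source": "C", "sink": "B"},
                # B already merged away at t=100 < 500
                {"time": 100, "kind": "divergence", "source": "B", "sink": "A"},
            ],
        }
        with pytest.raises(ModelError):
            build_model(spec)

    def test_yaml_round_trip(self, tmp_path):
        from demosfs.models import load_model, save_model

        for m in (catalog.model_e1(), catalog.model_g2()):
            p = tmp_path / f"{m.name}.yaml"
            save_model(m, p)
            m2 = load_model(p)
            assert m2 == m  # exact round trip

    def test_unknown_binding_rejected(self):
        spec = {
            "populations": [{"name": "A", "island_group": "X", "N_current": 100}],
            "free_params": [
                {"name": "T", "bounds": [1, 10], "slots": [{"kind": "event_time", "label": "Z"}]}
            ],
        }
        with pytest.raises(ModelError):
            build_model(spec)


class TestWithParams:
    def test_round_trip(self):
        m = catalog.model_g2()
        vals = m.param_values()
        m2 = m.with_params({"T1": 30000.0, "m_Muk": 5e-5})
        got = m2.param_values()
        assert got["T1"] == 30000.0 and got["m_Muk"] == 5e-5
        assert got["T2"] == vals["T2"]
        # symmetric slot applied both directions
        assert m2.migration.rates[("Sm", "STm")] == 5e-5
        assert m2.migration.rates[("STm", "Sm")] == 5e-5

    def test_infeasible_values_raise(self):
        m = catalog.model_g2()
        # reduction older than the deme's divergence is structurally invalid
        assert not m.is_feasible({"Tred": 90_000.0})

    def test_restrict_keeps_subset(self):
        m = catalog.model_e1().restrict(["T1", "T2"])
        assert [p.name for p in m.free_params] == ["T1", "T2"]
        with pytest.raises(ModelError):
            m.restrict(["nope"])


class TestEnumeration:
    def test_three_taxa_give_four_orderings(self):
        # 3 strictly ordered rooted histories + the simultaneous trichotomy
        assert len(enumerate_topologies(["A", "B", "C"])) == 4

    def test_two_taxa_give_one(self):
        assert len(enumerate_topologies(["A", "B"])) == 1

    def test_four_taxa_count_matches_multifurcating_tree_number(self):
        # rooted multifurcating labelled topologies on 4 leaves
        assert len(enumerate_topologies(list("ABCD"))) == 26

    def test_constraint_shrinks_candidate_set(self):
        full = enumerate_topologies(list("ABCD"))
        constrained = enumerate_topologies(list("ABCD"), [{"A", "B"}])
        # trees containing clade {A,B} = (trees on {AB, C, D}) = 4
        assert len(constrained) == 4 < len(full)
        assert all(frozenset("AB") in t.clades() for t in constrained)

    def test_ids_unique_and_deterministic(self):
        t1 = enumerate_topologies(list("ABCD"))
        t2 = enumerate_topologies(list("DCBA"))
        assert [t.id for t in t1] == [t.id for t in t2]
        assert len({t.id for t in t1}) == len(t1)

    def test_unknown_constraint_taxon_rejected(self):
        with pytest.raises(ModelError):
            enumerate_topologies(["A", "B"], [{"A", "Z"}])

    def test_candidates_are_valid_models(self):
        pops = [Population(n, "X", 2, 1000) for n in "ABC"]
        cands = enumerate_candidates(["A", "B", "C"], pops)
        assert len(cands) == 4
        for m in cands:
            assert sum(e.kind == "divergence" for e in m.events) == 2
            assert m.free_params  # fittable times

    def test_time_bracket_respects_nesting(self):
        m = catalog.model_e1()
        # ST's split must stay older than ST's expansion event (14,040 gen)
        lo, hi = m.time_bracket("T1")
        assert lo == pytest.approx(14_040) and hi == 1e5
        # SG's merge into S must fall between SD->SG (T4) and S->P (T2)
        lo3, hi3 = m.time_bracket("T3")
        assert lo3 == pytest.approx(14_840)
        assert hi3 == pytest.approx(15_380)
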