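"""Filters, missing-data bootstrap, 2D-mSFS construction and I/O."""

import numpy as np
import pytest

from demosfs import coalsim
from demosfs.coalsim import MISSING, fold_2d
from demosfs.models import ModelError
from demosfs.sfs import (
    FilterConfig,
    SFS2D,
    build_2d_msfs,
    fill_missing_bootstrap,
    filter_sites,
    read_popmap,
    read_sfs,
    read_vcf,
    write_fsc_obs,
    write_sfs,
)

from conftest import make_matrix, make_two_deme

M = MISSING
POPS2 = ["A"] * 3 + ["B"] * 3


class TestFilterSites:
    def test_hand_checked_five_site_fixture(self):
        # two populations of 3 diploids; r=0.8, p=2, min_mac=1, max_obs_het=0.5
        g = make_matrix(
            [
                [0, M, M, 0, 0, 1],  # pop A genotyping rate 1/3 < 0.8 -> out
                [0, 0, 0, 0, 0, 0],  # monomorphic, mac 0 < 1 -> out
                [1, 1, 1, 1, 1, 0],  # observed het 5/6 > 0.5 -> out
                [0, 0, 1, 0, 0, 0],  # passes every rule
                [2, 2, 1, 2, 2, 2],  # mac 1, het 1/6 -> passes
            ],
            POPS2,
        )
        cfg = FilterConfig(r=0.8, p=2, min_mac=1, max_obs_het=0.5)
        kept = filter_sites(g, cfg)
        assert [s.chrom for s in kept.sites] == ["c3", "c4"]

    def test_het_boundary(self):
        # het exactly 0.5 is retained; 0.6 removed (direct application)
        g = make_matrix([[1, 1, 1, 0, 0, 2], [1, 1, 1, 1, 0, 2]], POPS2)
        kept = filter_sites(g, FilterConfig(r=0.0, p=1, min_mac=0, max_obs_het=0.5))
        assert [s.chrom for s in kept.sites] == ["c0"]

    def test_mac_boundary_monomorphic(self):
        g = make_matrix([[0, 0, 0, 0, 0, 0]], POPS2)
        assert filter_sites(g, FilterConfig(r=0, p=1, min_mac=1)).n_sites == 0
        assert filter_sites(g, FilterConfig(r=0, p=1, min_mac=0)).n_sites == 1

    def test_overall_rate(self):
        g = make_matrix([[0, 1, M, M, M, M], [0, 1, 0, 0, M, M]], POPS2)
        cfg = FilterConfig(r=0, p=1, min_mac=0, max_obs_het=1.0, overall_rate=0.5)
        assert [s.chrom for s in filter_sites(g, cfg).sites] == ["c1"]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        geno = rng.choice([M, 0, 1, 2], size=(200, 6), p=[0.2, 0.4, 0.2, 0.2])
        g = make_matrix(geno, POPS2)
        cfg = FilterConfig(r=0.8, p=2, min_mac=1, max_obs_het=0.5)
        once = filter_sites(g, cfg)
        twice = filter_sites(once, cfg)
        assert once == twice

    def test_config_validation(self):
        with pytest.raises(ModelError):
            FilterConfig(r=1.5)
        with pytest.raises(ModelError):
            FilterConfig(min_mac=-1)
        with pytest.raises(ModelError):
            FilterConfig(p=0)


class TestBootstrapFill:
    def test_no_missing_is_identity(self):
        out = fill_missing_bootstrap(np.array([0, 1, 2]), 6, seed=0)
        assert sorted(out) == [0, 0, 0, 1, 1, 1]  # the observed alleles, untouched

    def test_all_reference_stays_reference(self):
        out = fill_missing_bootstrap(np.array([0, 0, M]), 6, seed=0)
        assert out.sum() == 0 and len(out) == 6

    def test_fill_frequency_matches_observed(self):
        # observed genotypes {0, 1} give alleles {0, 0, 0, 1}: each filled
        # haplotype carries allele 1 with probability 1/4
        hits = 0
        n = 5_000
        for s in range(n):
            out = fill_missing_bootstrap(np.array([0, 1, M]), 6, seed=s)
            assert 1 <= out.sum() <= 3  # one observed 1 plus 0-2 filled
            hits += int(out.sum() - 1)
        p = hits / (2 * n)
        se = np.sqrt((1 / 4) * (3 / 4) / (2 * n))
        assert abs(p - 1 / 4) < 3.29 * se  # central 99.9% interval

    def test_genotype_level_fill_draws_pairs(self):
        out = fill_missing_bootstrap(
            np.array([2, M]), 4, seed=1, genotype_level=True
        )
        assert out.sum() == 4  # only hom-alt genotypes observed -> filled pair 1/1

    def test_target_smaller_than_observed_rejected(self):
        with pytest.raises(ModelError):
            fill_missing_bootstrap(np.array([0, 1]), 2, seed=0)


class TestBuild2D:
    def test_single_site_direct_count(self):
        # 2+2 diploids, alt copies (1, 0): pooled 1/8 -> cell (1, 0)
        g = make_matrix([[1, 0, 0, 0]], ["A", "A", "B", "B"])
        s = build_2d_msfs(g, "A", "B")
        assert s.counts[1, 0] == 1 and s.total == 1

    def test_transpose_symmetry_with_missing_data(self):
        m = make_two_deme(free_time=False)
        g = coalsim.simulate_genotypes(m, 800, seed=3)
        g = coalsim.apply_missingness(g, 0.15, seed=9)
        ab = build_2d_msfs(g, "A", "B", seed=42)
        ba = build_2d_msfs(g, "B", "A", seed=42)
        assert np.array_equal(ab.counts, ba.counts.T)

    def test_brute_force_recount(self):
        # independent per-site loop with pooled-minor folding
        rng = np.random.default_rng(17)
        geno = rng.choice([0, 1, 2], size=(20, 6), p=[0.55, 0.3, 0.15])
        g = make_matrix(geno, POPS2)
        s = build_2d_msfs(g, "A", "B")
        expected = np.zeros((7, 7))
        for row in geno:
            a, b = int(row[:3].sum()), int(row[3:].sum())
            if 2 * (a + b) > 12:
                a, b = 6 - a, 6 - b
            expected[a, b] += 1
        assert np.array_equal(s.counts, expected)

    def test_conservation_with_exclusions(self):
        # one site has no genotyped individual in pop B -> excluded and logged
        g = make_matrix([[0, 1, 0, M, M, M], [0, 1, 0, 0, 0, 0]], POPS2)
        s = build_2d_msfs(g, "A", "B", seed=1)
        assert s.n_excluded == 1
        assert s.total + s.n_excluded == g.n_sites

    def test_bootstrap_completion_converges_with_vanishing_missingness(self):
        m = make_two_deme(free_time=False)
        g = coalsim.simulate_genotypes(m, 3000, seed=12)
        full = build_2d_msfs(g, "A", "B", seed=5).counts

        def dist(rate):
            gm = coalsim.apply_missingness(g, rate, seed=8)
            s = build_2d_msfs(gm, "A", "B", seed=5)
            return np.abs(s.counts - full).sum() / full.sum()

        assert dist(0.0) == 0.0
        assert dist(0.05) < dist(0.2)

    def test_fold_idempotent_and_validated(self):
        rng = np.random.default_rng(3)
        raw = rng.random((5, 7))
        once = fold_2d(raw)
        assert np.allclose(fold_2d(once), once)
        with pytest.raises(ModelError):
            SFS2D(("A", "B"), 4, 6, raw)  # unfolded table rejected
        SFS2D(("A", "B"), 4, 6, once)

    def test_same_population_twice_rejected(self):
        g = make_matrix([[0, 1, 0, 0, 0, 0]], POPS2)
        with pytest.raises(ModelError):
            build_2d_msfs(g, "A", "A")


class TestIO:
    def test_vcf_round_trip(self, tmp_path):
        m = make_two_deme(free_time=False)
        g = coalsim.simulate_genotypes(m, 300, seed=2)
        g = coalsim.apply_missingness(g, 0.1, seed=3)
        vcf = tmp_path / "x.vcf"
        pm = tmp_path / "x.popmap"
        coalsim.write_vcf(g, vcf)
        coalsim.write_popmap(g, pm)
        g2 = read_vcf(vcf, str(pm))
        assert np.array_equal(g.genotypes, g2.genotypes)
        assert g.individuals == g2.individuals
        assert g.populations == g2.populations
        assert [s.is_variable for s in g.sites] == [s.is_variable for s in g2.sites]

    def test_missing_code_round_trip(self, tmp_path):
        g = make_matrix([[M, 1, 0, 2, 0, 0]], POPS2)
        vcf = tmp_path / "m.vcf"
        coalsim.write_vcf(g, vcf)
        g2 = read_vcf(vcf, dict(zip(g.individuals, g.populations)))
        assert g2.genotypes[0, 0] == M

    def test_multiallelic_skipped(self, tmp_path):
        m = make_two_deme(free_time=False)
        g = coalsim.simulate_genotypes(m, 10, seed=2)
        vcf = tmp_path / "multi.vcf"
        coalsim.write_vcf(g, vcf)
        lines = vcf.read_text().splitlines()
        body = [i for i, l in enumerate(lines) if not l.startswith("#")]
        cols = lines[body[4]].split("\t")
        cols[4] = "T,C"  # make one record multi-allelic
        lines[body[4]] = "\t".join(cols)
        vcf.write_text("\n".join(lines) + "\n")
        g2 = read_vcf(vcf, dict(zip(g.individuals, g.populations)))
        assert g2.n_sites == 9

    def test_sfs_table_round_trip(self, tmp_path):
        g = make_matrix([[1, 0, 0, 0], [0, 0, 1, 1]], ["A", "A", "B", "B"])
        s = build_2d_msfs(g, "A", "B")
        p = tmp_path / "sfs.tsv"
        write_sfs(s, p, extra_comments=["seed=1"])
        s2 = read_sfs(p)
        assert s2.pair == s.pair and np.array_equal(s.counts, s2.counts)

    def test_fsc_obs_layout(self, tmp_path):
        g = make_matrix([[1, 0, 0, 0]], ["A", "A", "B", "B"])
        s = build_2d_msfs(g, "A", "B")
        p = tmp_path / "pair_jointMAFpop1_0.obs"
        write_fsc_obs(s, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "1 observations"
        assert len(lines) == 2 + s.n2 + 1  # header + labels + one row per class
        # rows are the second population; cell (d1_0, d0_1) holds count 1
        assert float(lines[2].split("\t")[2]) == 1.0

    def test_popmap_reader(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("i1\tA\n# comment\ni2\tB\n\n")
        assert read_popmap(p) == {"i1": "A", "i2": "B"}
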