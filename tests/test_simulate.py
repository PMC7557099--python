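"""Synthetic cohort generator: determinism, limits, closed-form checks."""

import numpy as np
import pytest

from pgxstrat import SimConfig, expected_pairwise_fst, simulate_cohort
from pgxstrat.divergence import pairwise_fst
from pgxstrat.simulate import SimConfigError


def _point_mass_alphas():
    return ((1000.0, 0.01, 0.01), (0.01, 1000.0, 0.01), (0.01, 0.01, 1000.0))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_per_group=(40, 40, 40), n_variants=80, n_pgx=8, seed=42)
        c1, t1 = simulate_cohort(cfg)
        c2, t2 = simulate_cohort(cfg)
        np.testing.assert_array_equal(c1.genotypes, c2.genotypes)
        np.testing.assert_array_equal(c1.ancestry, c2.ancestry)
        assert list(c1.sire_labels) == list(c2.sire_labels)
        np.testing.assert_array_equal(t1.ancestral_freqs, t2.ancestral_freqs)

    def test_different_seeds_differ(self):
        cfg_a = SimConfig(n_per_group=(40, 40, 40), n_variants=80, n_pgx=8, seed=1)
        cfg_b = SimConfig(n_per_group=(40, 40, 40), n_variants=80, n_pgx=8, seed=2)
        g1 = simulate_cohort(cfg_a)[0].genotypes
        g2 = simulate_cohort(cfg_b)[0].genotypes
        assert not np.array_equal(g1, g2, equal_nan=True)


class TestDegenerateLimits:
    def test_fixed_allele_in_point_mass_group(self):
        """alpha near a point mass + f=(1,0,0) forces dosage 2 in that group."""
        v = 20
        cfg = SimConfig(
            n_per_group=(30, 30, 30),
            dirichlet_alphas=_point_mass_alphas(),
            n_variants=v, n_pgx=0, missing_rate=0.0,
            ancestral_freqs=np.tile([1.0, 0.0, 0.0], (v, 1)),
            seed=3,
        )
        cohort, truth = simulate_cohort(cfg)
        group0 = truth.true_group == 0
        assert (cohort.genotypes[group0] == 2).all()
        assert (cohort.genotypes[truth.true_group == 1] == 0).all()

    def test_equal_freqs_make_ancestry_irrelevant(self):
        """f = 0.5 in all continents: pooled frequency 0.5 +- binomial error."""
        v = 50
        cfg = SimConfig(
            n_per_group=(100, 100, 100), n_variants=v, n_pgx=0,
            missing_rate=0.0,
            ancestral_freqs=np.full((v, 3), 0.5), seed=4,
        )
        cohort, _ = simulate_cohort(cfg)
        pooled = cohort.genotypes.mean(axis=0) / 2
        se = np.sqrt(0.25 / (2 * 300))
        assert (np.abs(pooled - 0.5) < 4 * se).mean() > 0.95

    def test_degenerate_configs_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_cohort(SimConfig(n_per_group=(0, 10, 10)))
        with pytest.raises(SimConfigError):
            simulate_cohort(SimConfig(n_variants=0))
        with pytest.raises(SimConfigError):
            simulate_cohort(SimConfig(n_variants=10, n_pgx=20))


class TestStatisticalStructure:
    def test_mean_ancestry_converges_to_dirichlet_mean(self):
        """Law of large numbers: group mean ancestry -> alpha/sum(alpha)."""
        cfg = SimConfig(n_per_group=(5000, 5000, 5000), n_variants=2, n_pgx=0,
                        seed=5)
        cohort, truth = simulate_cohort(cfg)
        alphas = np.asarray(cfg.dirichlet_alphas)
        expected = alphas / alphas.sum(axis=1, keepdims=True)
        for g in range(3):
            observed = cohort.ancestry[truth.true_group == g].mean(axis=0)
            np.testing.assert_allclose(observed, expected[g], atol=0.01)

    def test_group_frequencies_match_closed_form(self):
        """Observed group frequencies within 3 binomial SE of p_g = sum a*f."""
        v = 30
        freqs = np.tile([0.9, 0.1, 0.5], (v, 1))
        cfg = SimConfig(
            n_per_group=(2000, 2000, 2000),
            dirichlet_alphas=_point_mass_alphas(),
            n_variants=v, n_pgx=0, missing_rate=0.0,
            ancestral_freqs=freqs, seed=6,
        )
        cohort, truth = simulate_cohort(cfg)
        for g in range(3):
            p_g = truth.expected_group_freqs[:, g]
            obs = cohort.genotypes[truth.true_group == g].mean(axis=0) / 2
            se = np.sqrt(p_g * (1 - p_g) / (2 * 2000))
            assert (np.abs(obs - p_g) <= 3 * se + 1e-12).all()

    def test_mislabel_rate_reflected_in_sire(self):
        cfg = SimConfig(n_per_group=(2000, 2000, 2000), n_variants=2, n_pgx=0,
                        mislabel_rate=0.2, seed=7)
        cohort, truth = simulate_cohort(cfg)
        true_names = np.array(cfg.group_names, dtype=object)[truth.true_group]
        frac_flipped = (cohort.sire_labels != true_names).mean()
        assert frac_flipped == pytest.approx(0.2, abs=0.02)

    def test_pgx_subset_has_both_modes_and_inflated_divergence(self):
        cfg = SimConfig(n_per_group=(50, 50, 50), n_variants=400, n_pgx=40, seed=8)
        cohort, truth = simulate_cohort(cfg)
        modes = {v.pgx.mode for v in cohort.variants if v.pgx}
        assert modes == {"additive", "dominant"}
        f = truth.ancestral_freqs
        gap = f.max(axis=1) - f.min(axis=1)
        div = np.zeros(400, bool)
        div[truth.pgx_divergent_indices] = True
        assert len(truth.pgx_divergent_indices) == round(
            cfg.pgx_divergent_fraction * cfg.n_pgx
        )
        assert set(truth.pgx_divergent_indices) <= set(truth.pgx_indices)
        assert gap[div].min() >= cfg.min_pgx_gap
        assert gap[div].mean() > gap[~div].mean()


class TestExpectedFst:
    def test_known_values(self):
        """Equal freqs -> 0; fixed difference -> 1; 0.2/0.8 -> 0.36."""
        from pgxstrat.simulate import SimTruth

        expected = np.array([[0.3, 0.3], [1.0, 0.0], [0.2, 0.8]])
        truth = SimTruth(
            group_names=("White", "Black"),
            group_sizes=(100, 100),
            true_group=np.repeat([0, 1], 100),
            true_ancestry=np.zeros((200, 3)),
            ancestral_freqs=np.zeros((3, 3)),
            expected_group_freqs=expected,
            pgx_indices=np.array([], dtype=int),
            pgx_divergent_indices=np.array([], dtype=int),
        )
        res = expected_pairwise_fst(truth, "White", "Black")
        assert res.fst[0] == pytest.approx(0.0, abs=1e-12)
        assert res.fst[1] == pytest.approx(1.0, abs=1e-12)
        assert res.h_s_bar[2] == pytest.approx(0.32)
        assert res.h_t[2] == pytest.approx(0.5)
        assert res.fst[2] == pytest.approx(0.36)

    def test_observed_fst_tracks_expected(self):
        """Median |observed - expected| FST below 0.02 at n = 2000/group."""
        cfg = SimConfig(
            n_per_group=(2000, 2000, 2000),
            dirichlet_alphas=_point_mass_alphas(),
            n_variants=200, n_pgx=0, missing_rate=0.0, seed=10,
        )
        cohort, truth = simulate_cohort(cfg)
        expected = expected_pairwise_fst(truth, "White", "Black").fst
        g = cohort.genotypes
        mask_a = truth.true_group == 0
        mask_b = truth.true_group == 1
        p_a = g[mask_a].mean(axis=0) / 2
        p_b = g[mask_b].mean(axis=0) / 2
        observed = pairwise_fst(p_a, 2 * mask_a.sum(), p_b, 2 * mask_b.sum()).fst
        dev = np.abs(observed - expected)
        assert np.nanmedian(dev) < 0.02
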