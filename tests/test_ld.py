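"""Haplotype-frequency EM and LD statistics."""

import numpy as np
import pytest
from scipy.special import xlogy

from apoeld.data import MISSING
from apoeld.ld import (
    GenotypeCounts9,
    em_hapfreqs,
    em_hapfreqs_batch,
    ld_from_hapfreqs,
    ld_pair,
    r_from_freqs_batch,
    r_variance,
    tabulate_counts,
    tabulate_counts_matrix,
)


# -- independent oracles -----------------------------------------------------


def genotype_cell_probs(p11, p10, p01, p00):
    """9-cell genotype probabilities under random union of haplotypes."""
    return np.array(
        [
            p00**2,
            2 * p00 * p01,
            p01**2,
            2 * p00 * p10,
            2 * p11 * p00 + 2 * p10 * p01,
            2 * p11 * p01,
            p10**2,
            2 * p11 * p10,
            p11**2,
        ]
    )


def grid_ml(flat_counts, coarse=0.01, fine=5e-4):
    """Coarse-to-fine grid maximization of the genotype multinomial
    likelihood over the haplotype-frequency 3-simplex (resolution <= 1e-3).

    Independent of the EM implementation: evaluates the likelihood on an
    explicit grid and returns the argmax.
    """

    def loglik_at(p11, p10, p01):
        p00 = 1.0 - p11 - p10 - p01
        cells = genotype_cell_probs(p11, p10, p01, p00)
        with np.errstate(divide="ignore", invalid="ignore"):
            return xlogy(flat_counts[:, None], cells.T if cells.ndim == 2 else cells)

    def evaluate(grid_axes):
        g11, g10, g01 = np.meshgrid(*grid_axes, indexing="ij")
        g11, g10, g01 = g11.ravel(), g10.ravel(), g01.ravel()
        ok = g11 + g10 + g01 <= 1.0 + 1e-12
        g11, g10, g01 = g11[ok], g10[ok], g01[ok]
        g00 = np.clip(1.0 - g11 - g10 - g01, 0.0, 1.0)
        cells = genotype_cell_probs(g11, g10, g01, g00)  # (9, G)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = xlogy(flat_counts[:, None], cells).sum(axis=0)
        k = int(np.nanargmax(ll))
        return np.array([g11[k], g10[k], g01[k], g00[k]])

    ax = np.arange(0.0, 1.0 + coarse / 2, coarse)
    best = evaluate([ax, ax, ax])
    axes = [
        np.clip(np.arange(b - 1.5 * coarse, b + 1.5 * coarse + fine / 2, fine), 0, 1)
        for b in best[:3]
    ]
    return evaluate(axes)


def random_model_table(rng, n_max=200):
    """Random genotype count table drawn from a random haplotype pool."""
    while True:
        pool = rng.dirichlet(np.ones(4))
        n = int(rng.integers(50, n_max + 1))
        flat = rng.multinomial(n, genotype_cell_probs(*pool))
        pA = (2 * (flat[6] + flat[7] + flat[8]) + flat[3] + flat[4] + flat[5]) / (2 * n)
        pB = (2 * (flat[2] + flat[5] + flat[8]) + flat[1] + flat[4] + flat[7]) / (2 * n)
        if 0 < pA < 1 and 0 < pB < 1:
            return flat


# -- tabulation --------------------------------------------------------------


class TestTabulate:
    def test_diagonal(self):
        c = tabulate_counts(np.array([0, 1, 2]), np.array([0, 1, 2]))
        assert c.counts[0, 0] == c.counts[1, 1] == c.counts[2, 2] == 1
        assert c.n == 3

    def test_missing_dropped(self):
        c = tabulate_counts(np.array([0, MISSING]), np.array([0, 0]))
        assert c.counts[0, 0] == 1 and c.n == 1

    def test_matches_nested_loop(self):
        rng = np.random.default_rng(2)
        d1 = rng.integers(-1, 3, size=100)
        d2 = rng.integers(-1, 3, size=100)
        expected = np.zeros((3, 3), int)
        for a, b in zip(d1, d2):
            if a != MISSING and b != MISSING:
                expected[a, b] += 1
        c = tabulate_counts(d1, d2)
        np.testing.assert_array_equal(c.counts, expected)

    def test_matrix_form_matches_pairwise(self):
        rng = np.random.default_rng(3)
        anchor = rng.integers(-1, 3, size=80)
        mat = rng.integers(-1, 3, size=(80, 7))
        batch = tabulate_counts_matrix(anchor, mat)
        for j in range(7):
            np.testing.assert_array_equal(
                batch[j].reshape(3, 3), tabulate_counts(anchor, mat[:, j]).counts
            )

    def test_no_complete_pairs_errors(self):
        with pytest.raises(ValueError):
            tabulate_counts(np.array([MISSING]), np.array([0]))


# -- EM ---------------------------------------------------------------------


class TestEm:
    def test_phase_unambiguous_perfect_ld(self):
        c = GenotypeCounts9(np.array([[50, 0, 0], [0, 0, 0], [0, 0, 50]]))
        h = em_hapfreqs(c)
        assert h.p11 == pytest.approx(0.5, abs=1e-9)
        assert h.p00 == pytest.approx(0.5, abs=1e-9)
        assert h.p10 == pytest.approx(0.0, abs=1e-9)
        assert ld_from_hapfreqs(h, c.n).r == pytest.approx(1.0)

    def test_phase_unambiguous_independence(self):
        c = GenotypeCounts9(np.array([[25, 0, 25], [0, 0, 0], [25, 0, 25]]))
        h = em_hapfreqs(c)
        for f in (h.p11, h.p10, h.p01, h.p00):
            assert f == pytest.approx(0.25, abs=1e-9)
        assert ld_from_hapfreqs(h, c.n).r == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_ml(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            flat = random_model_table(rng)
            h = em_hapfreqs(GenotypeCounts9(flat.reshape(3, 3)))
            oracle = grid_ml(flat)
            est = np.array([h.p11, h.p10, h.p01, h.p00])
            assert np.abs(est - oracle).max() < 2e-3, (flat, est, oracle)

    def test_loglik_non_decreasing_each_iteration(self):
        from apoeld.ld import _em_one_start, _loglik, _marginals, _starts

        rng = np.random.default_rng(23)
        for _ in range(10):
            flat = random_model_table(rng)[None, :]
            pA, pB = _marginals(flat)
            p = _starts(pA, pB)[0]
            prev = _loglik(flat, p)[0]
            for _ in range(50):
                p, ll, _, _ = _em_one_start(flat, p, tol=0.0, max_iter=1)
                assert ll[0] >= prev - 1e-9
                prev = ll[0]

    def test_no_double_het_equals_counting_estimator(self):
        # without the ambiguous cell, haplotype counts are fully determined
        flat = np.array([10, 5, 3, 7, 0, 4, 6, 2, 8])
        h = em_hapfreqs(GenotypeCounts9(flat.reshape(3, 3)))
        two_n = 2 * flat.sum()
        assert h.p11 == pytest.approx((2 * 8 + 2 + 4) / two_n, abs=1e-12)
        assert h.p10 == pytest.approx((2 * 6 + 2 + 7) / two_n, abs=1e-12)
        assert h.p01 == pytest.approx((2 * 3 + 4 + 5) / two_n, abs=1e-12)
        assert h.p00 == pytest.approx((2 * 10 + 5 + 7) / two_n, abs=1e-12)
        assert h.iterations <= 2

    def test_r_antisymmetric_under_allele_relabel(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            flat = random_model_table(rng)
            tab = flat.reshape(3, 3)
            r1 = ld_pair_from_table(tab)
            r2 = ld_pair_from_table(tab[:, ::-1])  # swap SNP-2 allele labels
            assert r2 == pytest.approx(-r1, abs=1e-9)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            em_hapfreqs(GenotypeCounts9(np.array([[50, 0, 0], [50, 0, 0], [0, 0, 0]])))

    def test_estimator_consistency_on_known_truth(self):
        # estimated r within +-0.03 of truth in >=95% of seeded replicates
        p_true = np.array([0.15, 0.1, 0.05, 0.7])
        pA, pB = 0.25, 0.20
        r_true = (0.15 - pA * pB) / np.sqrt(pA * (1 - pA) * pB * (1 - pB))
        rng = np.random.default_rng(101)
        cellp = genotype_cell_probs(*p_true)
        tables = rng.multinomial(5000, cellp, size=200)
        p, _, _, cv = em_hapfreqs_batch(tables)
        rs = r_from_freqs_batch(p)
        assert cv.all()
        assert (np.abs(rs - r_true) <= 0.03).mean() >= 0.95


def ld_pair_from_table(tab):
    h = em_hapfreqs(GenotypeCounts9(np.asarray(tab)))
    return ld_from_hapfreqs(h, int(np.asarray(tab).sum())).r


# -- LD statistics -----------------------------------------------------------


class TestLdStats:
    def test_perfect_ld_closed_form(self):
        h = em_hapfreqs(GenotypeCounts9(np.array([[50, 0, 0], [0, 0, 0], [0, 0, 50]])))
        res = ld_from_hapfreqs(h, 100)
        assert res.D == pytest.approx(0.25)
        assert res.r == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(100.0)

    def test_chi2_is_r_squared_times_n_bit_exact(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            flat = random_model_table(rng)
            tab = GenotypeCounts9(flat.reshape(3, 3))
            h = em_hapfreqs(tab)
            res = ld_from_hapfreqs(h, tab.n)
            assert res.chi2 == res.r * res.r * tab.n  # exact identity

    def test_chi2_closed_form_example(self):
        # r = 0.1, n = 400 -> chi2 = 4, p ~ 0.0455
        from scipy import stats

        assert 0.1**2 * 400 == pytest.approx(4.0)
        assert float(stats.chi2.sf(4.0, 1)) == pytest.approx(0.0455, abs=2e-4)

    def test_d_and_r_match_first_principles(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            h = _freqs(p)
            res = ld_from_hapfreqs(h, 500)
            pA = p[0] + p[1]
            pB = p[0] + p[2]
            D = p[0] - pA * pB
            r = D / np.sqrt(pA * (1 - pA) * pB * (1 - pB))
            assert res.D == pytest.approx(D, abs=1e-12)
            assert res.r == pytest.approx(r, abs=1e-12)


def _freqs(p):
    from apoeld.ld import HapFreqs

    return HapFreqs(
        p11=p[0], p10=p[1], p01=p[2], p00=1 - p[0] - p[1] - p[2],
        loglik=0.0, iterations=1, converged=True,
    )


# -- variance ----------------------------------------------------------------


class TestRVariance:
    def test_decreases_with_sample_size(self):
        p_true = (0.15, 0.1, 0.05, 0.7)
        cellp = genotype_cell_probs(*p_true)
        variances = []
        for n in (100, 1000, 10000):
            flat = np.round(cellp * n).astype(int)
            tab = GenotypeCounts9(flat.reshape(3, 3))
            h = em_hapfreqs(tab)
            variances.append(r_variance(h, tab))
        assert variances[0] > variances[1] > variances[2]

    def test_agrees_with_bootstrap_phase_unambiguous(self):
        rng = np.random.default_rng(53)
        # strong LD keeps double heterozygotes nearly phase-determined
        cellp = genotype_cell_probs(0.28, 0.02, 0.02, 0.68)
        flat = rng.multinomial(1000, cellp)
        tab = GenotypeCounts9(flat.reshape(3, 3))
        h = em_hapfreqs(tab)
        v_delta = r_variance(h, tab)
        boot = rng.multinomial(1000, flat / 1000, size=400)
        p, _, _, _ = em_hapfreqs_batch(boot)
        rs = r_from_freqs_batch(p)
        v_boot = float(np.nanvar(rs, ddof=1))
        assert v_delta == pytest.approx(v_boot, rel=0.15)

    def test_independence_case_matches_one_over_n(self):
        # classical limit Var(r) ~ (1-r^2)^2 / n = 1/n at r = 0
        n = 1000
        flat = np.round(genotype_cell_probs(0.25, 0.25, 0.25, 0.25) * n).astype(int)
        tab = GenotypeCounts9(flat.reshape(3, 3))
        h = em_hapfreqs(tab)
        assert r_variance(h, tab) == pytest.approx(1.0 / n, rel=0.10)

    def test_boundary_falls_back_to_bootstrap(self):
        # perfect LD puts the estimate on the simplex boundary
        tab = GenotypeCounts9(np.array([[50, 0, 0], [0, 0, 0], [0, 0, 50]]))
        h = em_hapfreqs(tab)
        v = r_variance(h, tab, seed=7)
        assert np.isfinite(v) and v >= 0
        assert v == r_variance(h, tab, seed=7)  # seeded determinism
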