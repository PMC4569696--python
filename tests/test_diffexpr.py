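"""NB differential expression: oracles, calibration, power, and invariances."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isletmir.counts_io import CountMatrix
from isletmir.diffexpr import (
    NormalizationError,
    adjust_bh,
    estimate_dispersions,
    estimate_size_factors,
    run_de,
)
from isletmir.diffexpr import test_differential as nb_test  # avoid test collection

from conftest import make_count_matrix


# --- independent oracles ----------------------------------------------------

def brute_force_size_factors(counts: np.ndarray) -> list[float]:
    """Literal median-of-ratios over all-positive rows, via statistics.median."""
    n_genes, n_samples = counts.shape
    geomeans = []
    for g in range(n_genes):
        row = counts[g]
        if all(v > 0 for v in row):
            prod = 1.0
            for v in row:
                prod *= float(v)
            geomeans.append((g, prod ** (1.0 / n_samples)))
    return [
        statistics.median([counts[g, j] / gm for g, gm in geomeans])
        for j in range(n_samples)
    ]


def brute_force_bh(pvalues: list[float]) -> list[float]:
    """Step-up rule by direct enumeration: q_i = min over j>=rank(i) of m*p_(j)/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for rank, i in enumerate(order, start=1):
        candidates = []
        for later_rank, j in enumerate(order, start=1):
            if later_rank >= rank:
                candidates.append(min(1.0, m * pvalues[j] / later_rank))
        q[i] = min(candidates)
    return q


# --- size factors -----------------------------------------------------------

class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix([[4, 4], [9, 9]], ["A", "B"])
        assert estimate_size_factors(cm).tolist() == pytest.approx([1.0, 1.0])

    def test_hand_median_of_ratios(self):
        cm = make_count_matrix([[2, 4], [4, 8], [6, 12]], ["A", "B"])
        sf = estimate_size_factors(cm)
        assert sf.tolist() == pytest.approx([0.7071, 1.4142], abs=5e-5)

    def test_single_sample_factor_is_one(self):
        cm = make_count_matrix([[5], [9]], ["A"])
        assert estimate_size_factors(cm).tolist() == pytest.approx([1.0])

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            counts = rng.integers(0, 200, size=(10, 4))
            counts[rng.integers(0, 10)] += 1  # ensure an all-positive row exists
            counts[:3] += 1
            cm = make_count_matrix(counts, ["A", "A", "B", "B"])
            got = estimate_size_factors(cm).to_numpy()
            want = np.array(brute_force_size_factors(counts))
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_matches_pydeseq2(self):
        # pydeseq2 interpolates median ties geometrically, so use an odd
        # number of reference genes where the two conventions coincide
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(9)
        counts = 1 + rng.poisson(rng.lognormal(4, 1, 61)[:, None]
                                 * np.array([1.0, 1.6, 0.6, 1.2]), size=(61, 4))
        cm = make_count_matrix(counts, ["A", "A", "B", "B"])
        _, sf = pydeseq2.deseq2_norm(pd.DataFrame(counts.T))
        np.testing.assert_allclose(
            estimate_size_factors(cm).to_numpy(), np.asarray(sf), rtol=1e-10
        )

    def test_relative_scale_equivariance(self):
        # scaling one library by c multiplies its factor relative to the others by c
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 300, size=(50, 4))
        base = estimate_size_factors(make_count_matrix(counts, ["A", "A", "B", "B"]))
        scaled_counts = counts.copy()
        scaled_counts[:, 2] *= 5
        scaled = estimate_size_factors(
            make_count_matrix(scaled_counts, ["A", "A", "B", "B"])
        )
        np.testing.assert_allclose(
            (scaled.iloc[2] / scaled.iloc[0]) / (base.iloc[2] / base.iloc[0]),
            5.0, rtol=1e-10,
        )

    def test_no_reference_gene_raises(self):
        cm = make_count_matrix([[0, 5], [3, 0]], ["A", "B"])
        with pytest.raises(NormalizationError):
            estimate_size_factors(cm)


# --- dispersions ------------------------------------------------------------

class TestDispersions:
    def _simulate(self, alpha, n_per_group, n_genes, seed):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(np.log(300), 0.8, n_genes)
        n = 2 * n_per_group
        if alpha > 0:
            lam = rng.gamma(1 / alpha, mu[:, None] * alpha, size=(n_genes, n))
        else:
            lam = np.broadcast_to(mu[:, None], (n_genes, n))
        counts = rng.poisson(lam)
        return make_count_matrix(counts, ["A"] * n_per_group + ["B"] * n_per_group)

    def test_nb_parameter_recovery(self):
        cm = self._simulate(alpha=0.2, n_per_group=10, n_genes=800, seed=31)
        disp = estimate_dispersions(cm, estimate_size_factors(cm), ("A", "B"))
        assert 0.1 <= disp["raw_dispersion"].median() <= 0.3

    def test_poisson_data_yields_near_zero_raw(self):
        cm = self._simulate(alpha=0.0, n_per_group=10, n_genes=800, seed=32)
        disp = estimate_dispersions(cm, estimate_size_factors(cm), ("A", "B"))
        assert (disp["raw_dispersion"] == 0).mean() > 0.4
        assert disp["used_dispersion"].median() <= 0.05

    def test_constant_gene_raw_zero_and_max_rule(self):
        cm = make_count_matrix([[7, 7, 7, 7], [3, 9, 2, 14]], ["A", "A", "B", "B"])
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersions(cm, sf, ("A", "B"))
        assert disp.loc[0, "raw_dispersion"] == 0.0
        assert (disp["used_dispersion"]
                == disp[["raw_dispersion", "fitted_dispersion"]].max(axis=1)).all()

    def test_no_replicates_anywhere_raises(self):
        cm = make_count_matrix([[3, 5]], ["A", "B"])
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(cm, pd.Series(1.0, index=cm.sample_ids), ("A", "B"))


# --- the test itself --------------------------------------------------------

def _null_matrix(n_genes=2000, alpha=0.1, n_per_group=4, seed=12345):
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(200), 1.0, n_genes)
    lam = rng.gamma(1 / alpha, mu[:, None] * alpha, size=(n_genes, 2 * n_per_group))
    counts = rng.poisson(lam)
    return make_count_matrix(counts, ["A"] * n_per_group + ["B"] * n_per_group)


class TestDifferentialTest:
    def test_identical_groups_are_null(self):
        cm = make_count_matrix(
            [[10, 20, 10, 20], [50, 60, 50, 60]], ["A", "A", "B", "B"]
        )
        de = run_de(cm, ("A", "B"))
        assert de["log2fc"].tolist() == [0.0, 0.0]
        assert de["pvalue"].tolist() == [1.0, 1.0]

    def test_type_one_error_calibration(self):
        de = run_de(_null_matrix(), ("A", "B"))
        frac = (de["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_fourfold(self):
        rng = np.random.default_rng(777)
        n, alpha = 2000, 0.05
        mu_a = np.full(n, 100.0)
        mu_b = mu_a.copy()
        planted = rng.choice(n, 200, replace=False)
        mu_b[planted] *= 4
        lam_a = rng.gamma(1 / alpha, mu_a[:, None] * alpha, size=(n, 4))
        lam_b = rng.gamma(1 / alpha, mu_b[:, None] * alpha, size=(n, 4))
        counts = np.hstack([rng.poisson(lam_a), rng.poisson(lam_b)])
        cm = make_count_matrix(counts, ["A"] * 4 + ["B"] * 4)
        de = run_de(cm, ("A", "B"))
        assert (de["pvalue"].to_numpy()[planted] < 1e-3).mean() >= 0.90

    def test_swapping_contrast_negates_lfc_keeps_p(self):
        cm = _null_matrix(n_genes=100, seed=5)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf, ("A", "B"))
        ab = nb_test(cm, sf, disp, ("A", "B"))
        ba = nb_test(cm, sf, disp, ("B", "A"))
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"], rtol=1e-9)

    def test_normal_approximation_matches_exact_at_boundary(self):
        cm = _null_matrix(n_genes=200, seed=6)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf, ("A", "B"))
        exact = nb_test(cm, sf, disp, ("A", "B"), exact_total_limit=10 ** 9)
        approx = nb_test(cm, sf, disp, ("A", "B"), exact_total_limit=0)
        assert np.max(np.abs(exact["pvalue"] - approx["pvalue"])) < 0.02

    def test_all_zero_gene_not_tested(self):
        cm = make_count_matrix([[0, 0, 0, 0], [9, 8, 7, 9]], ["A", "A", "B", "B"])
        de = run_de(cm, ("A", "B"))
        assert de.loc[0, "status"] == "not_tested"
        assert de.loc[0, "pvalue"] == 1.0


# --- BH adjustment ----------------------------------------------------------

class TestBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03]).tolist() == [0.03]

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            adjust_bh([0.2, 1.3])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    def test_matches_brute_force_enumeration(self, pvals):
        got = adjust_bh(pvals)
        want = brute_force_bh(pvals)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_bounds_and_order_preservation(self, pvals):
        q = adjust_bh(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        # monotone: larger p never gets smaller q
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
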