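"""Differential-expression oracles: size factors, NB Wald fit, BH, gating."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from exoscreen.data import CASE, CONTROL, CountMatrix, SampleMeta
from exoscreen.diffexpr import (DEGate, bh_adjust, nb_wald, select_de,
                                size_factors)
from exoscreen.simulate import simulate_cohort


def _cm(counts):
    counts = np.asarray(counts, float)
    return CountMatrix(
        np.array([f"f{i}" for i in range(counts.shape[0])], dtype=object),
        np.array([f"s{j}" for j in range(counts.shape[1])], dtype=object),
        counts)


def _meta(y):
    y = np.asarray(y)
    return SampleMeta(np.array([f"s{j}" for j in range(len(y))], dtype=object),
                      np.array([CASE if v else CONTROL for v in y], dtype=object),
                      np.array(["c"] * len(y), dtype=object))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm([[4.0, 4.0], [10.0, 10.0]])
        np.testing.assert_allclose(size_factors(cm), [1.0, 1.0])

    def test_hand_computed_two_by_two(self):
        # geometric means (4, 4); ratios column 0 = 0.5, column 1 = 2.0
        cm = _cm([[2.0, 8.0], [2.0, 8.0]])
        np.testing.assert_allclose(size_factors(cm), [0.5, 2.0])

    def test_doubling_a_column_doubles_its_factor(self, rng):
        base = rng.integers(1, 100, size=(50, 3)).astype(float)
        f1 = size_factors(_cm(base))
        doubled = base.copy()
        doubled[:, 1] *= 2.0
        f2 = size_factors(_cm(doubled))
        # geometric means change by 2^(1/3); all ratios scale together
        scale = 2.0 ** (1.0 / 3.0)
        np.testing.assert_allclose(f2[1] / f1[1], 2.0 / scale, rtol=1e-10)
        np.testing.assert_allclose(f2[0] / f1[0], 1.0 / scale, rtol=1e-10)

    def test_fallback_without_all_positive_feature(self):
        cm = _cm([[0.0, 8.0], [2.0, 0.0]])
        f = size_factors(cm)
        assert np.all(f > 0)


def _nb_negloglik(params, k, x, s, alpha):
    """Independent NB2 log-likelihood (natural-log parameters)."""
    b0, b1 = params
    mu = s * np.exp(b0 + b1 * x)
    r = 1.0 / alpha
    return -np.sum(stats.nbinom.logpmf(k, r, r / (r + mu)))


class TestNBWald:
    def test_matches_numerical_mle_with_known_dispersion(self):
        # toy feature, counts printed here, dispersion fixed at 0.3
        k = np.array([[12, 7, 20, 15, 9, 31, 3, 6, 2, 4, 1, 5]], float)
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        cm = _cm(np.vstack([k, np.full(12, 10.0)]))  # 2nd feature fixes factors
        meta = _meta(y)
        res = nb_wald(cm, meta, dispersions=np.array([0.3, 0.3]))
        s = res.attrs["size_factors"]
        opt = optimize.minimize(
            _nb_negloglik, x0=[2.0, -1.0], args=(k.ravel(), y, s, 0.3),
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        ln2 = np.log(2.0)
        assert res.loc[0, "log2fc"] == pytest.approx(opt.x[1] / ln2, abs=1e-4)
        # expected Fisher information at the oracle optimum
        mu = s * np.exp(opt.x[0] + opt.x[1] * y)
        w = mu / (1 + 0.3 * mu)
        i00, i01 = w.sum(), w[y == 1].sum()
        se_b1 = np.sqrt(i00 / (i00 * i01 - i01**2))
        assert res.loc[0, "wald_stat"] == pytest.approx(opt.x[1] / se_b1,
                                                        rel=1e-3)

    def test_poisson_limit(self):
        """At dispersion -> 0 the Wald statistic matches a Poisson GLM."""
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 15)
        k = rng.poisson(np.where(y == 1, 30, 12), size=(4, 30)).astype(float)
        cm = _cm(k)
        meta = _meta(y)
        res = nb_wald(cm, meta, dispersions=np.full(4, 1e-8))
        s = res.attrs["size_factors"]
        for i in range(4):
            glm = sm.GLM(k[i], sm.add_constant(y.astype(float)),
                         family=sm.families.Poisson(),
                         offset=np.log(s)).fit()
            z_oracle = glm.params[1] / glm.bse[1]
            assert res.loc[i, "wald_stat"] == pytest.approx(z_oracle, rel=1e-4)

    def test_null_simulation_pvalues_uniform(self):
        cm, meta, *_ = simulate_cohort(50, 50, 500, 0, seed=13)
        res = nb_wald(cm, meta)
        assert np.abs(res["log2fc"]).median() < 0.3
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.035)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_planted_log2fc_recovered_within_ci(self):
        lfc = [-3.8, -3.43, 2.0]
        cm, meta, _, truth = simulate_cohort(80, 160, 300, 3,
                                             planted_log2fc=lfc, seed=41)
        res = nb_wald(cm, meta).set_index("feature_id")
        for fid, planted in zip(truth.planted_features, lfc):
            est, se = res.loc[fid, "log2fc"], res.loc[fid, "se"]
            assert abs(est - planted) < 3 * se + 0.1

    def test_all_zero_feature_flagged(self):
        cm = _cm([[0, 0, 0, 0, 0, 0], [5, 6, 7, 8, 9, 10]])
        res = nb_wald(cm, _meta([0, 0, 0, 1, 1, 1]))
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "log2fc"] == 0.0
        assert bool(res.loc[0, "all_zero"])

    def test_requires_two_per_group(self):
        cm = _cm([[1, 2, 3]])
        with pytest.raises(Exception):
            nb_wald(cm, _meta([0, 0, 1]))

    def test_padj_never_below_p(self, small_cohort):
        cm, meta, *_ = small_cohort
        res = nb_wald(cm.subset_features(cm.feature_ids[:100]), meta)
        assert np.all(res["padj"] >= res["p"] - 1e-12)


def _bh_bruteforce(p):
    """min over j >= rank of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [min(p[order[j]] * m / (j + 1), 1.0)
                      for j in range(pos, m)]
        out[idx] = min(candidates)
    return out


class TestBH:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_values_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_bruteforce(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-12)

    def test_matches_bruteforce_large_vector(self, rng):
        p = rng.random(1000)
        np.testing.assert_allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-12)


class TestSelectDE:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "log2fc", "padj",
                                           "base_mean"])

    def test_strongly_downregulated_abundant_row_selected(self):
        tbl = self._table([("CXCL5-like", -3.80, 3.22e-58, 493.0)])
        assert select_de(tbl, DEGate()) == ["CXCL5-like"]

    def test_single_gate_failures(self):
        tbl = self._table([
            ("lfc_too_small", 1.0, 1e-10, 400.0),
            ("padj_too_big", -3.0, 0.06, 400.0),
            ("too_rare", -3.0, 1e-10, 49.0),
            ("boundary_lfc", 1.2, 1e-10, 400.0),   # strict: 1.2 not > 1.2
            ("pass_a", -2.0, 1e-4, 51.0),
            ("pass_b", 1.3, 0.049, 1000.0),
        ])
        assert select_de(tbl) == ["pass_a", "pass_b"]

    def test_order_invariant(self):
        tbl = self._table([
            ("a", -2.0, 1e-4, 60.0), ("b", 3.0, 1e-6, 80.0),
            ("c", 0.1, 0.9, 10.0)])
        fwd = select_de(tbl)
        rev = select_de(tbl.iloc[::-1].reset_index(drop=True))
        assert set(fwd) == set(rev)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_de(self._table([]))
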