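import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from schemabg.stats import (
    anova2_logrt,
    chi2_2x2,
    jzs_bf,
    jzs_bf_from_t,
    mann_whitney_w,
    normative_te,
    pearson_partial,
)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def brute_force_w(x, y):
    w = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                w += 1.0
            elif xi == yj:
                w += 0.5
    return w


class TestMannWhitney:
    def test_x_entirely_below_y(self):
        w, _ = mann_whitney_w([1, 2, 3], [10, 11, 12])
        assert w == 0.0

    def test_identical_samples_midpoint(self):
        x = [1.0, 2.0, 3.0, 4.0]
        w, _ = mann_whitney_w(x, list(x))
        assert w == len(x) ** 2 / 2

    def test_matches_brute_force_small(self):
        x, y = [1, 2, 5], [3, 4]
        w, _ = mann_whitney_w(x, y)
        assert w == brute_force_w(x, y) == 2.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 20), min_size=2, max_size=12),
        st.lists(st.integers(0, 20), min_size=2, max_size=12),
    )
    def test_convention_sum_property(self, x, y):
        wxy, _ = mann_whitney_w(x, y)
        wyx, _ = mann_whitney_w(y, x)
        assert wxy + wyx == pytest.approx(len(x) * len(y))
        assert wxy == pytest.approx(brute_force_w(x, y))

    def test_constant_pooled_sample_flagged(self):
        w, p = mann_whitney_w([2, 2], [2, 2, 2])
        assert w == 3.0
        assert math.isnan(p)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_w([], [1.0])


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

class TestChi2:
    def test_printed_gender_table(self):
        assert round(chi2_2x2([[9, 16], [8, 17]]), 3) == 0.089

    def test_expected_counts_give_zero(self):
        assert chi2_2x2([[10, 20], [10, 20]]) == pytest.approx(0.0)

    def test_diagonal_table(self):
        assert chi2_2x2([[10, 0], [0, 10]]) == pytest.approx(20.0)

    def test_transposition_and_swap_invariance(self):
        t = np.array([[3.0, 7.0], [11.0, 5.0]])
        base = chi2_2x2(t)
        assert chi2_2x2(t.T) == pytest.approx(base)
        assert chi2_2x2(t[::-1]) == pytest.approx(base)
        assert chi2_2x2(t[:, ::-1]) == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[0, 0], [1, 2]])


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def quadrature_oracle_bf10(t, nx, ny, scale=0.5, n_grid=200_001):
    """Independent fixed-grid (trapezoid, substitution g = u/(1-u)) integration."""
    nu = nx + ny - 2
    n_eff = nx * ny / (nx + ny)
    r2 = scale * scale
    u = np.linspace(1e-9, 1 - 1e-9, n_grid)
    g = u / (1 - u)
    jac = 1.0 / (1 - u) ** 2
    log_prior = (0.5 * np.log(r2 / 2.0) - math.lgamma(0.5)
                 - 1.5 * np.log(g) - r2 / (2 * g))
    log_lik = (-0.5 * np.log1p(n_eff * g)
               - (nu + 1) / 2 * np.log1p(t * t / ((1 + n_eff * g) * nu)))
    numer = np.trapezoid(np.exp(log_prior + log_lik) * jac, u)
    denom = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return numer / denom


class TestJzs:
    def test_null_favored_at_zero_effect(self):
        assert jzs_bf([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bf_from_t(t, 20, 20) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(10):
            t = float(rng.uniform(-4, 4))
            nx = int(rng.integers(5, 40))
            ny = int(rng.integers(5, 40))
            got = jzs_bf_from_t(t, nx, ny)
            want = quadrature_oracle_bf10(t, nx, ny)
            assert got == pytest.approx(want, rel=1e-4)

    def test_matches_pingouin(self):
        import pingouin as pg

        for t, nx, ny in [(2.0, 25, 25), (0.5, 10, 14), (-1.7, 30, 20)]:
            assert jzs_bf_from_t(t, nx, ny) == pytest.approx(
                float(pg.bayesfactor_ttest(t, nx, ny, paired=False, r=0.5)), rel=1e-3)

    def test_ordinal_consistency_with_p(self):
        from scipy import stats as sps

        ts = np.linspace(0.0, 4.0, 9)
        bf01 = [1.0 / jzs_bf_from_t(t, 25, 25) for t in ts]
        ps = [2 * sps.t.sf(t, 48) for t in ts]
        assert all(b1 > b2 for b1, b2 in zip(bf01, bf01[1:]))
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf([1.0, 1.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# Mixed ANOVA on log RT
# ---------------------------------------------------------------------------

def make_rt_frame(group_means):
    rows = []
    for g, (pos_mean, neg_mean, n) in group_means.items():
        for k in range(n):
            pid = f"{g}{k}"
            rows.append({"participant": pid, "group": g, "feedback": "pos",
                         "rt": pos_mean + 7.0 * ((k % 5) - 2)})
            rows.append({"participant": pid, "group": g, "feedback": "neg",
                         "rt": neg_mean + 7.0 * ((k % 5) - 2)})
    return pd.DataFrame(rows)


def anova_oracle(df):
    """Brute-force SS decomposition for the balanced 2x2 mixed design (on log rt)."""
    d = df.copy()
    d["y"] = np.log(d["rt"])
    grand = d["y"].mean()
    n_subj = d["participant"].nunique()
    subj_means = d.groupby("participant")["y"].mean()
    subj_group = d.groupby("participant")["group"].first()
    group_means = d.groupby("group")["y"].mean()
    cond_means = d.groupby("feedback")["y"].mean()
    cell_means = d.groupby(["group", "feedback"])["y"].mean()
    counts = d.groupby("group")["participant"].nunique()
    ss_group = sum(2 * counts[g] * (group_means[g] - grand) ** 2 for g in counts.index)
    ss_subj = sum(2 * (subj_means[s] - group_means[subj_group[s]]) ** 2
                  for s in subj_means.index)
    ss_cond = sum(n_subj * (cond_means[c] - grand) ** 2 for c in cond_means.index)
    ss_inter = sum(
        counts[g] * (cell_means[(g, c)] - group_means[g] - cond_means[c] + grand) ** 2
        for g in counts.index for c in cond_means.index
    )
    ss_total = ((d["y"] - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_cond - ss_inter
    df_err = n_subj - 2
    return {
        "group": (ss_group / 1) / (ss_subj / df_err),
        "feedback": (ss_cond / 1) / (ss_err / df_err),
        "interaction": (ss_inter / 1) / (ss_err / df_err),
        "ss": (ss_group, ss_subj, ss_cond, ss_inter, ss_err, ss_total),
    }


class TestMixedAnova:
    def test_null_data_all_f_small(self, rng):
        df = make_rt_frame({"younger": (500, 500, 8), "older": (500, 500, 8)})
        df["rt"] += rng.normal(0, 1, len(df))
        out = anova2_logrt(df)
        assert (out["F"] < 2.5).all()

    def test_additive_dataset_no_interaction(self):
        # pure main effects on the log scale; per-subject deviations sum to
        # zero within every group x condition cell, so the interaction SS is
        # exactly zero by construction while the residual SS is not
        base = {"younger": (6.0, 6.2), "older": (6.4, 6.6)}
        dev = {"pos": [0.05, -0.05, 0.03, -0.03], "neg": [-0.02, 0.02, -0.04, 0.04]}
        rows = []
        for g, (pos, neg) in base.items():
            for k in range(4):
                pid = f"{g}{k}"
                rows.append({"participant": pid, "group": g, "feedback": "pos",
                             "rt": math.exp(pos + dev["pos"][k])})
                rows.append({"participant": pid, "group": g, "feedback": "neg",
                             "rt": math.exp(neg + dev["neg"][k])})
        out = anova2_logrt(pd.DataFrame(rows))
        assert out.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["group", "F"] > 10
        assert out.loc["feedback", "F"] > 10

    def test_degrees_of_freedom(self):
        df = make_rt_frame({"younger": (400, 500, 9), "older": (600, 640, 7)})
        out = anova2_logrt(df)
        assert (out["df1"] == 1).all()
        assert (out["df2"] == 9 + 7 - 2).all()

    def test_matches_brute_force_decomposition(self, rng):
        df = make_rt_frame({"a": (420, 470, 4), "b": (520, 610, 4)})
        df["rt"] *= np.exp(rng.normal(0, 0.05, len(df)))
        out = anova2_logrt(df)
        oracle = anova_oracle(df)
        for effect in ("group", "feedback", "interaction"):
            assert out.loc[effect, "F"] == pytest.approx(oracle[effect], rel=1e-6)
        ss_g, ss_s, ss_c, ss_i, ss_e, ss_t = oracle["ss"]
        assert ss_g + ss_s + ss_c + ss_i + ss_e == pytest.approx(ss_t)

    def test_missing_cell_rejected(self):
        df = make_rt_frame({"a": (400, 500, 4), "b": (600, 640, 4)})
        with pytest.raises(ValueError):
            anova2_logrt(df.iloc[:-1])


# ---------------------------------------------------------------------------
# Correlations and the normative regression
# ---------------------------------------------------------------------------

class TestCorrelations:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        c = rng.normal(size=20)
        r, _ = pearson_partial(x, x, c)
        assert r == pytest.approx(1.0)

    def test_independent_covariate_keeps_r(self, rng):
        x = rng.normal(size=5000)
        y = x + rng.normal(size=5000)
        c = rng.normal(size=5000)
        r, rp = pearson_partial(x, y, c)
        assert rp == pytest.approx(r, abs=0.02)

    def test_residual_regression_oracle(self, rng):
        x = rng.normal(size=60)
        c = 0.5 * x + rng.normal(size=60)
        y = 0.7 * x - 0.3 * c + rng.normal(size=60)
        _, rp = pearson_partial(x, y, c)
        rx = x - np.polyval(np.polyfit(c, x, 1), c)
        ry = y - np.polyval(np.polyfit(c, y, 1), c)
        assert rp == pytest.approx(float(np.corrcoef(rx, ry)[0, 1]), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_partial([1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1])


class TestNormativeRegression:
    def test_age_65(self):
        assert normative_te(65, 14) == pytest.approx(17.71)

    def test_age_85(self):
        assert normative_te(85, 14) == pytest.approx(22.31)

    def test_intercept(self):
        assert normative_te(0, 0) == pytest.approx(6.12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            normative_te(-1, 10)
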