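"""Statistics battery: rank tests, chi-square, JZS Bayes factors, mixed ANOVA,
(partial) correlations, and the published normative regression for
spatial-anticipation total errors.

Conventions
-----------
* ``mann_whitney_w`` is on the U/W scale in ``[0, n_x * n_y]`` (ties
  mid-ranked): a sample entirely below the other scores 0, identical equal
  sized samples score ``n**2 / 2``.
* ``chi2_2x2`` is the Pearson statistic *without* continuity correction.
* Bayes factors use a zero-centered Cauchy prior on effect size with scale
  1/2 by default; ``BF01 = 1 / BF10`` exactly.
"""

from __future__ import annotations

import math
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

DEFAULT_CAUCHY_SCALE = 0.5


# ---------------------------------------------------------------------------
# Rank / frequency tests
# ---------------------------------------------------------------------------

def mann_whitney_w(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed Mann-Whitney test; returns ``(W, p)``.

    ``W`` counts pairs ``(x_i, y_j)`` with ``x_i > y_j`` (ties count 1/2);
    the p-value uses the normal approximation with tie correction.  If the
    pooled sample is constant, the p-value is undefined and ``nan`` is
    returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, math.nan
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(table: Sequence[Sequence[float]]) -> float:
    """Pearson chi-square statistic for a 2x2 table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) <= 0) or np.any(obs.sum(axis=1) <= 0):
        raise ValueError("zero margin")
    stat, _, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat)


# ---------------------------------------------------------------------------
# JZS Bayes factor (two-sample)
# ---------------------------------------------------------------------------

def jzs_bf_from_t(
    t: float,
    n_x: int,
    n_y: int,
    scale: float = DEFAULT_CAUCHY_SCALE,
) -> float:
    """Two-sample JZS ``BF10`` from a t statistic, by numerical integration.

    The Cauchy prior on standardized effect size (location 0, scale
    ``scale``) is integrated out via its inverse-gamma mixture
    representation over the g-prior (Rouder-style marginal likelihood).
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("need at least two observations per sample")
    nu = n_x + n_y - 2
    n_eff = n_x * n_y / (n_x + n_y)
    r2 = scale * scale

    def integrand(g: float) -> float:
        # inverse-gamma(1/2, r2/2) density x marginal likelihood ratio term
        log_prior = (
            0.5 * math.log(r2 / 2.0)
            - special.gammaln(0.5)
            - 1.5 * math.log(g)
            - r2 / (2.0 * g)
        )
        log_lik = (
            -0.5 * math.log1p(n_eff * g)
            - (nu + 1) / 2.0 * math.log1p(t * t / ((1.0 + n_eff * g) * nu))
        )
        return math.exp(log_prior + log_lik)

    numer, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    log_denom = -(nu + 1) / 2.0 * math.log1p(t * t / nu)
    return numer / math.exp(log_denom)


def jzs_bf(
    x: Sequence[float],
    y: Sequence[float],
    scale: float = DEFAULT_CAUCHY_SCALE,
) -> float:
    """Two-sample JZS ``BF10`` for the samples ``x`` and ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    if sx2 == 0 and sy2 == 0:
        raise ValueError("zero pooled variance")
    sp2 = ((x.size - 1) * sx2 + (y.size - 1) * sy2) / (x.size + y.size - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / x.size + 1 / y.size))
    return jzs_bf_from_t(t, x.size, y.size, scale=scale)


# ---------------------------------------------------------------------------
# Mixed ANOVA on log RT
# ---------------------------------------------------------------------------

def anova2_logrt(data: pd.DataFrame) -> pd.DataFrame:
    """Log-transformed 2x2 mixed ANOVA (group between, prior feedback within).

    ``data`` is long-format with columns ``participant``, ``group``,
    ``feedback`` and ``rt`` (one mean RT per participant per feedback
    condition).  Returns a table indexed by effect (``group``, ``feedback``,
    ``interaction``) with columns ``F``, ``df1``, ``df2``, ``p`` and ``np2``.
    """
    import pingouin as pg

    required = {"participant", "group", "feedback", "rt"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = data.groupby(["participant", "feedback"]).size().unstack(fill_value=0)
    if counts.shape[1] != 2 or (counts != 1).any().any():
        raise ValueError("each participant needs exactly one mean RT per feedback condition")
    df = data.copy()
    if (df["rt"] <= 0).any():
        raise ValueError("RTs must be positive for the log transform")
    df["logrt"] = np.log(df["rt"])
    aov = pg.mixed_anova(
        data=df, dv="logrt", within="feedback", subject="participant", between="group"
    )
    aov = aov.set_index("Source")
    out = {}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    for src, name in [("group", "group"), ("feedback", "feedback"), ("Interaction", "interaction")]:
        row = aov.loc[src]
        out[name] = {
            "F": float(row["F"]),
            "df1": int(row["DF1"]),
            "df2": int(row["DF2"]),
            "p": float(row[p_col]),
            "np2": float(row["np2"]),
        }
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariate: Sequence[float],
) -> Tuple[float, float]:
    """Pearson ``r(x, y)`` and the first-order partial correlation given ``covariate``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.size == y.size == c.size):
        raise ValueError("inputs must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    for arr, name in [(x, "x"), (y, "y"), (c, "covariate")]:
        if arr.std() == 0:
            raise ValueError(f"zero variance in {name}")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xc = float(np.corrcoef(x, c)[0, 1])
    r_yc = float(np.corrcoef(y, c)[0, 1])
    denom = math.sqrt((1 - r_xc**2) * (1 - r_yc**2))
    r_partial = (r_xy - r_xc * r_yc) / denom
    return r_xy, r_partial


# ---------------------------------------------------------------------------
# Normative regression and convenience wrappers
# ---------------------------------------------------------------------------

def normative_te(age: float, education: float) -> float:
    """Published normative regression for spatial-anticipation total errors."""
    if age < 0 or education < 0:
        raise ValueError("age and education must be non-negative")
    return 6.12 + 0.23 * age - 0.24 * education


def normality_screen(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (reporting convenience)."""
    res = sps.shapiro(np.asarray(sample, dtype=float))
    return float(res.statistic), float(res.pvalue)


def group_comparison_report(
    cohort: pd.DataFrame,
    measures: Sequence[str],
    group_col: str = "group",
    groups: Tuple[str, str] = ("younger", "older"),
) -> pd.DataFrame:
    """Per-measure between-group battery: means/SDs, W, p, BF10, Shapiro p.

    Mirrors the structure of the performance-measure analyses: a
    Mann-Whitney test and a JZS Bayes factor per measure.
    """
    a = cohort[cohort[group_col] == groups[0]]
    b = cohort[cohort[group_col] == groups[1]]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    rows: Dict[str, Dict[str, float]] = {}
    for m in measures:
        x = a[m].to_numpy(dtype=float)
        y = b[m].to_numpy(dtype=float)
        w, p = mann_whitney_w(x, y)
        try:
            bf10 = jzs_bf(x, y)
        except ValueError:
            bf10 = math.nan
        _, shapiro_p = normality_screen(np.concatenate([x, y]))
        rows[m] = {
            f"mean_{groups[0]}": x.mean(),
            f"sd_{groups[0]}": x.std(ddof=1),
            f"mean_{groups[1]}": y.mean(),
            f"sd_{groups[1]}": y.std(ddof=1),
            "W": w,
            "p": p,
            "BF10": bf10,
            "shapiro_p": shapiro_p,
        }
    return pd.DataFrame(rows).T
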