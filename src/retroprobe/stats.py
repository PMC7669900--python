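"""Resampling statistics for small, non-normal trauma and outcome samples.

Trauma metrics (ITA, ITR, dead-cell counts) from insertion experiments
fail normality screens, so group comparisons use non-parametric bootstrap
t-tests with pooled resampling: the two samples are pooled, resampled
with replacement to the original group sizes, and the Welch t statistic
recomputed per replicate to build the null distribution.  Families of
pairwise comparisons are Bonferroni-corrected.  Binary insertion-success
outcomes are compared with Fisher's exact test on 2x2 tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "lilliefors_test",
    "bootstrap_t_test",
    "pairwise_posthoc",
    "fisher_exact",
    "bonferroni",
    "significance_stars",
    "summarize_conditions",
    "success_rates",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with multiplicity bookkeeping."""

    statistic: float
    p_raw: float
    method: str
    n_comparisons: int = 1
    bootstrap_replicates: int | None = None
    seed: int | None = None

    @property
    def p_adjusted(self) -> float:
        """Bonferroni-adjusted p: ``min(1, p_raw * n_comparisons)``."""
        return min(1.0, self.p_raw * self.n_comparisons)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Successes/failures for two groups; rows are groups."""

    a: int  # group 1 successes
    b: int  # group 1 failures
    c: int  # group 2 successes
    d: int  # group 2 failures

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be >= 0")
        if (self.a + self.b) == 0 or (self.c + self.d) == 0:
            raise ValueError("both row margins must be > 0")


def _ks_distance_to_fitted_normal(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to the normal with estimated mean/SD."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def lilliefors_test(
    sample: np.ndarray, n_mc: int = 10000, seed: int = 0
) -> TestResult:
    """Lilliefors normality screen with a Monte-Carlo null.

    The statistic is the KS distance between the empirical CDF and the
    normal CDF with mean and SD estimated from the sample; because the
    parameters are estimated, the null distribution of the distance is
    simulated (``n_mc`` standard-normal samples of the same size) rather
    than taken from the plain KS tables.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("lilliefors_test needs n >= 5")
    if x.std(ddof=1) == 0:
        raise ValueError("sample is constant; normality is degenerate")
    d_obs = _ks_distance_to_fitted_normal(x)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, x.size))
    # vectorised KS distance per simulated sample
    mu = sims.mean(axis=1, keepdims=True)
    sd = sims.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((sims - mu) / sd, axis=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, x.size + 1) / x.size
    d_null = np.maximum((i - cdf).max(axis=1), (cdf - (i - 1 / x.size)).max(axis=1))
    p = (1 + int(np.count_nonzero(d_null >= d_obs))) / (n_mc + 1)
    return TestResult(d_obs, p, "lilliefors-mc", bootstrap_replicates=n_mc, seed=seed)


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = math.sqrt(vx / nx + vy / ny)
    if denom == 0:
        return 0.0
    return float((x.mean() - y.mean()) / denom)


def bootstrap_t_test(
    x: np.ndarray, y: np.ndarray, B: int = 10000, seed: int = 0
) -> TestResult:
    """Two-sided bootstrap t-test with pooled resampling.

    The observed statistic is the Welch (unequal-variance) t.  Under the
    null both groups share a distribution, so replicates resample the
    pooled data with replacement to the original group sizes and
    recompute t; ``p = (1 + #{|t*| >= |t_obs|}) / (B + 1)``, which never
    returns exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    # sorting the pool makes the null distribution independent of the
    # order the samples were passed in (exact x<->y symmetry at equal n)
    pooled = np.sort(np.concatenate([x, y]))
    if pooled.var(ddof=1) == 0:
        warnings.warn("zero pooled variance; returning p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "bootstrap-t-pooled", bootstrap_replicates=B, seed=seed)
    t_obs = _welch_t(x, y)
    rng = np.random.default_rng(seed)
    nx, ny = x.size, y.size
    idx = rng.integers(0, pooled.size, size=(B, nx + ny))
    samples = pooled[idx]
    xs, ys = samples[:, :nx], samples[:, nx:]
    vx = xs.var(axis=1, ddof=1)
    vy = ys.var(axis=1, ddof=1)
    denom = np.sqrt(vx / nx + vy / ny)
    num = xs.mean(axis=1) - ys.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    p = (1 + int(np.count_nonzero(np.abs(t_star) >= abs(t_obs)))) / (B + 1)
    return TestResult(t_obs, p, "bootstrap-t-pooled", bootstrap_replicates=B, seed=seed)


def significance_stars(p: float) -> str:
    """Figure-style stars: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


def pairwise_posthoc(
    groups: dict[str, np.ndarray], B: int = 10000, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """All-pairs bootstrap t-tests with Bonferroni correction.

    Returns symmetric DataFrames ``{"p_raw", "p_adjusted", "stars"}``
    indexed by group label; the Bonferroni factor is the number of pairs
    actually tested.  Groups with fewer than 2 observations are skipped
    with a warning.
    """
    usable = {}
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            warnings.warn(f"group {label!r} has n < 2; skipped", stacklevel=2)
            continue
        usable[label] = v
    labels = list(usable)
    if len(labels) < 2:
        raise ValueError("need at least two groups with n >= 2")
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    m = len(pairs)
    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    p_raw = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (i, j), s in zip(pairs, seeds):
        res = bootstrap_t_test(usable[labels[i]], usable[labels[j]], B=B, seed=int(s))
        p_raw.iloc[i, j] = p_raw.iloc[j, i] = res.p_raw
    p_adj = p_raw.map(lambda p: bonferroni(p, m) if np.isfinite(p) else np.nan)
    stars = p_adj.map(lambda p: significance_stars(p) if np.isfinite(p) else "")
    return {"p_raw": p_raw, "p_adjusted": p_adj, "stars": stars}


def fisher_exact(table: ContingencyTable2x2, n_comparisons: int = 1) -> TestResult:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    With margins fixed, each admissible table has an exact hypergeometric
    probability; the two-sided p sums the probabilities of all tables no
    more probable than the observed one (the minimum-likelihood rule).
    Probabilities are formed from exact integer binomials, so ties at
    the observed probability are resolved exactly.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = math.comb(n, c1)
    w_obs = weights[a - lo]
    p = sum(w for w in weights if w <= w_obs) / total
    if b * c == 0:
        odds = math.inf if a * d > 0 else (0.0 if a + d > 0 else math.nan)
    else:
        odds = (a * d) / (b * c)
    return TestResult(odds, min(1.0, p), "fisher-exact", n_comparisons=n_comparisons)


def summarize_conditions(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group descriptive table: n, mean, SD, median, quartiles.

    SD is left blank for singleton groups; ``mean_sd`` formats the usual
    ``mean +/- SD`` string.
    """
    if not groups:
        raise ValueError("no groups to summarize")
    rows = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        sd = float(v.std(ddof=1)) if v.size > 1 else np.nan
        rows.append(
            {
                "group": label,
                "n": v.size,
                "mean": float(v.mean()),
                "sd": sd,
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "mean_sd": (
                    f"{v.mean():.2f} ± {sd:.2f}" if np.isfinite(sd) else f"{v.mean():.2f}"
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def success_rates(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-group success counts and percentage rates from an outcome table."""
    if not {"group", "success"} <= set(outcomes.columns):
        raise ValueError("outcome table needs 'group' and 'success' columns")
    g = outcomes.groupby("group")["success"]
    df = pd.DataFrame(
        {"successes": g.sum().astype(int), "total": g.count().astype(int)}
    )
    df["rate_percent"] = 100.0 * df["successes"] / df["total"]
    return df
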