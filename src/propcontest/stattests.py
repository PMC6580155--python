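"""Statistical primitives for the overbidding pipeline.

Thin, explicitly-parameterized wrappers around scipy for the standard
tests (one-way ANOVA, Levene, Kruskal-Wallis, Fisher's exact), plus the
pieces with conventions worth pinning down here: the overbidding-rate
statistic, the summary-statistic entry point for one-sample t tests,
the Mann-Whitney normal approximation with tie and continuity
corrections (sign convention: z < 0 when the first sample tends
smaller), and a Gaussian KDE with the Silverman rule-of-thumb bandwidth
h = 0.9 * min(SD, IQR/1.34) * n^(-1/5).

Every test returns a :class:`TestResult`; degenerate inputs that leave
a statistic undefined yield an error-flagged result rather than NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DensityCurve",
    "overbidding_rate",
    "individual_overbidding",
    "one_sample_t",
    "two_sample_t",
    "oneway_anova",
    "bonferroni_adjust",
    "levene_test",
    "kruskal_wallis",
    "mann_whitney",
    "fisher_exact",
    "silverman_bandwidth",
    "silverman_kde",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    extras: dict = field(default_factory=dict)
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    def __str__(self) -> str:  # compact report line
        if not self.ok:
            return f"{self.method}: undefined ({self.error})"
        df = "" if self.df is None else f", df={self.df}"
        return f"{self.method}: stat={self.statistic:.4f}{df}, p={self.p_value:.4g}"


def _error_result(method: str, message: str) -> TestResult:
    return TestResult(method=method, statistic=float("nan"), df=None,
                      p_value=float("nan"), error=message)


# ---------------------------------------------------------------------------
# Overbidding statistics
# ---------------------------------------------------------------------------


def overbidding_rate(mean_expenditure: float, e_star: float) -> float:
    """Relative excess of a mean expenditure over equilibrium, (m - e*)/e*.

    Negative values indicate underbidding.
    """
    if not e_star > 0:
        raise ValueError(f"e_star must be positive, got {e_star}")
    return (mean_expenditure - e_star) / e_star


def individual_overbidding(bid: float, e_star: float) -> float:
    """Bid minus the equilibrium bid, in francs (the regression outcome)."""
    if e_star < 0:
        raise ValueError(f"e_star must be nonnegative, got {e_star}")
    return bid - e_star


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------


def one_sample_t(
    values: Sequence[float] | None = None,
    mu0: float = 0.0,
    summary: tuple[float, float, int] | None = None,
) -> TestResult:
    """Two-sided one-sample t test, from raw values or a (mean, sd, n) summary.

    Both entry points evaluate the same formula t = (mean - mu0)/(sd/sqrt(n)),
    so a raw sample and its own summary agree exactly.
    """
    if (values is None) == (summary is None):
        raise ValueError("pass exactly one of `values` or `summary`")
    if values is not None:
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least two observations")
        mean, sd, n = float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)
    else:
        mean, sd, n = float(summary[0]), float(summary[1]), int(summary[2])
        if n < 2:
            raise ValueError("need n >= 2")
    if not sd > 0:
        return _error_result("one-sample t", "zero sample standard deviation")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("one-sample t", float(t), float(df), float(p),
                      extras={"mean": mean, "sd": sd, "n": n, "mu0": mu0})


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pooled-variance Student t test (two-sided), df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return _error_result("two-sample t", "both groups are constant")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    return TestResult("two-sample t", float(t), float(df), float(p),
                      extras={"n_a": int(a.size), "n_b": int(b.size)})


# ---------------------------------------------------------------------------
# ANOVA family
# ---------------------------------------------------------------------------


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within, df (k-1, N-k)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least two observations")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    df = (float(k - 1), float(n_total - k))
    if all(np.ptp(a) == 0 for a in arrs):
        return _error_result("one-way ANOVA", "all observations within groups are constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrs)
    if not np.isfinite(f):
        return _error_result("one-way ANOVA", "F statistic undefined for this input")
    return TestResult("one-way ANOVA", float(f), df, float(p),
                      extras={"k": k, "n": n_total})


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Multiply each p by the number of comparisons, capped at 1."""
    ps = [float(p) for p in p_values]
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(p * m, 1.0) for p in ps]


def levene_test(groups: Sequence[Sequence[float]], center: str = "mean") -> TestResult:
    """Levene homogeneity-of-variance test (ANOVA on absolute deviations)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least two observations")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    if all(np.ptp(a) == 0 for a in arrs):
        return _error_result("Levene", "all groups are constant")
    w, p = sps.levene(*arrs, center=center)
    return TestResult("Levene", float(w), (float(k - 1), float(n_total - k)), float(p),
                      extras={"center": center})


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square reference, df k-1."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return _error_result("Kruskal-Wallis", "all observations are tied")
    h, p = sps.kruskal(*arrs)
    return TestResult("Kruskal-Wallis", float(h), float(len(arrs) - 1), float(p))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    continuity: bool = True,
) -> TestResult:
    """Mann-Whitney U with normal approximation (tie-corrected).

    Reports U for the first sample and z = (U - mu_U +- 1/2) / sigma_U
    (continuity correction toward zero, on by default); z < 0 when the
    first sample tends to be smaller.  Two-sided p from the normal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return _error_result("Mann-Whitney U", "all observations are tied")
    diff = u1 - mu
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("Mann-Whitney U", float(u1), None, float(p),
                      extras={"z": float(z), "n_a": n1, "n_b": n2,
                              "continuity": continuity})


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


def fisher_exact(table: Sequence[Sequence[float]]) -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided point-probability method.

    The p-value sums hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
        raise ValueError("cell counts must be nonnegative integers")
    arr = arr.astype(np.int64)
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult("Fisher exact", float(odds), None, float(p),
                      extras={"table": arr.tolist()})


# ---------------------------------------------------------------------------
# Kernel density
# ---------------------------------------------------------------------------


@dataclass
class DensityCurve:
    """A kernel density estimate on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def modes(self, rel_height: float = 0.05) -> np.ndarray:
        """Grid locations of interior local maxima of the curve.

        Maxima below ``rel_height`` times the global maximum are
        discarded: an isolated tail observation always produces a tiny
        kernel bump, which is not a mode in any substantive sense.
        """
        d = self.density
        is_max = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        is_max &= d[1:-1] >= rel_height * d.max()
        return self.grid[1:-1][is_max]

    def integral(self) -> float:
        """Trapezoid integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: Sequence[float]) -> float:
    """Silverman rule of thumb: h = 0.9 * min(SD, IQR/1.34) * n^(-1/5).

    If the IQR collapses to zero on a discrete-ish sample the SD alone
    is used, keeping the bandwidth positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two observations")
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("sample has zero spread; bandwidth undefined")
    q75, q25 = np.percentile(arr, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * arr.size ** (-1.0 / 5.0)


def silverman_kde(
    values: Sequence[float],
    grid: Sequence[float] | None = None,
    bounds: tuple[float, float] = (0.0, 80.0),
    n_grid: int = 321,
) -> DensityCurve:
    """Gaussian-kernel density with the Silverman bandwidth on a bid grid."""
    arr = np.asarray(values, dtype=float)
    h = silverman_bandwidth(arr)
    x = np.linspace(bounds[0], bounds[1], n_grid) if grid is None else np.asarray(grid, dtype=float)
    z = (x[:, None] - arr[None, :]) / h
    density = sps.norm.pdf(z).mean(axis=1) / h
    return DensityCurve(grid=x, density=density, bandwidth=float(h))
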