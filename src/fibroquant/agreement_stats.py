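"""Method-agreement statistics for paired fibrosis measurements.

Given per-slide fibrosis percentages from several methods measured on the
same slides — here the stereology reference, the colocalization and
pattern-recognition routes and the pathologist's visual score — this module
reproduces the classical agreement battery:

* summary statistics per method (mean, median, SD, range, min, max);
* a Pearson correlation matrix with two-sided p-values;
* Friedman's repeated-measures rank test across methods, with Wilcoxon
  signed-rank post-hoc pairs under a Bonferroni-adjusted alpha;
* ordinary least-squares regression of each method on the reference, raw and
  natural-log transformed;
* Bland-Altman agreement with the reference on the X axis (not the pairwise
  mean — the reference is treated as the criterion standard) and limits of
  agreement at mean difference +/- 2 SD.

Friedman and Wilcoxon are computed in-package with the standard tie-corrected
rank formulas so that degenerate inputs (identical columns, all-zero
differences) have documented behavior and the Wilcoxon Z carries the sign of
the rank-sum excess; scipy serves as an independent cross-check in the test
suite.  Measurements containing exact zeros are ln-transformed after adding a
fixed +1 percentage-point offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_histology import ParameterError


class ValidationError(ValueError):
    pass


#: Offset added before the natural-log transform (measurements may be 0).
LN_OFFSET = 1.0


@dataclass(frozen=True)
class MethodMeasurements:
    """Per-slide fibrosis percentages, one column per method."""

    data: pd.DataFrame  # index: slide_id; columns: method names; values: %

    def __post_init__(self):
        df = self.data
        if df.empty:
            raise ValidationError("measurements table is empty")
        values = df.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 100):
            raise ValidationError("fibrosis percentages must lie in [0, 100]")
        if {"pathologist_week0", "pathologist_week2", "pathologist_mean"} <= set(df.columns):
            expected = (df["pathologist_week0"] + df["pathologist_week2"]) / 2.0
            if not np.allclose(df["pathologist_mean"], expected, atol=1e-9):
                raise ValidationError("pathologist_mean must be the mean of the two readings")

    @property
    def n_slides(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def with_pathologist_mean(df: pd.DataFrame) -> pd.DataFrame:
    """Add the arithmetic mean of the two pathologist readings."""
    out = df.copy()
    out["pathologist_mean"] = (out["pathologist_week0"] + out["pathologist_week2"]) / 2.0
    return out


def summarize_methods(measurements: MethodMeasurements) -> pd.DataFrame:
    """Per-method mean, median, SD (n-1), range, min, max."""
    df = measurements.data
    rows = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        if v.size == 0:
            raise ValidationError(f"column {col!r} is empty")
        rows[col] = {
            "n": v.size,
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "range": float(np.max(v) - np.min(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }
    return pd.DataFrame(rows).T


def pearson_matrix(measurements: MethodMeasurements) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric Pearson r and two-sided p matrices (t with n-2 df).

    A zero-variance column yields NaN entries flagged by raising in strict
    contexts being undesirable; here undefined correlations are returned as
    NaN with the p-value NaN as well, never silently as a number.
    """
    df = measurements.data
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


@dataclass(frozen=True)
class FriedmanResult:
    chi_square: float
    df: int
    p_value: float


def friedman_test(measurements: MethodMeasurements, columns: list[str] | None = None) -> FriedmanResult:
    """Friedman's rank test across k matched method columns.

    Within each slide the k values are ranked (average ranks on ties); the
    tie-corrected statistic is
    ``chi2 = [12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C`` with
    ``C = 1 - sum(t^3 - t) / (n k (k^2 - 1))`` over tie groups.  When every
    row is fully tied both numerator and C vanish; the statistic is defined
    as 0 there (no evidence of any method difference).
    """
    cols = columns or list(measurements.data.columns)
    k = len(cols)
    block = measurements.data[cols].to_numpy(dtype=float)
    n = block.shape[0]
    if k < 3:
        raise ParameterError("Friedman test needs at least 3 methods")
    if n < 2:
        raise ParameterError("Friedman test needs at least 2 slides")
    ranks = np.apply_along_axis(stats.rankdata, 1, block)
    rank_sums = ranks.sum(axis=0)
    numerator = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in block:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if abs(numerator) < 1e-12 or correction <= 0:
        chi2 = 0.0
    else:
        chi2 = numerator / correction
    p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return FriedmanResult(chi_square=float(chi2), df=k - 1, p_value=p)


@dataclass(frozen=True)
class PairedComparison:
    pair: tuple[str, str]
    mean_difference: float
    sd_difference: float
    z_statistic: float
    p_value: float
    adjusted_alpha: float
    significant: bool
    degenerate: bool = False

    @property
    def name(self) -> str:
        return f"{self.pair[0]} - {self.pair[1]}"


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Signed-rank Z and two-sided p by normal approximation.

    Differences a-b; exact zeros dropped (Wilcoxon convention); tied absolute
    differences get average ranks; the variance carries the tie correction
    ``sum(t^3 - t)/48``; no continuity correction.  Z is signed: positive
    when positive differences dominate the rank sum, so reversing the pair
    flips its sign.  Returns (nan, nan) when every difference is zero.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return float("nan"), float("nan")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return float("nan"), float("nan")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def wilcoxon_pairs(
    measurements: MethodMeasurements,
    pairs: list[tuple[str, str]],
    family_alpha: float = 0.05,
) -> list[PairedComparison]:
    """Post-hoc Wilcoxon signed-rank tests under Bonferroni correction.

    The adjusted per-pair alpha is ``family_alpha / len(pairs)``; mean and SD
    of the raw (un-ranked) differences are reported alongside, matching how
    paired-comparison tables are usually printed.
    """
    if not pairs:
        raise ParameterError("pairs must be nonempty")
    alpha = family_alpha / len(pairs)
    out = []
    for a, b in pairs:
        x = measurements.column(a)
        y = measurements.column(b)
        d = x - y
        z, p = wilcoxon_signed_rank(x, y)
        degenerate = np.isnan(z)
        out.append(
            PairedComparison(
                pair=(a, b),
                mean_difference=float(np.mean(d)),
                sd_difference=float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
                z_statistic=z,
                p_value=p,
                adjusted_alpha=alpha,
                significant=bool((not degenerate) and p < alpha),
                degenerate=bool(degenerate),
            )
        )
    return out


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    transform: str  # "raw" | "ln"
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    residual_se: float = 0.0
    n: int = 0

    def confidence_band(self, x_new: np.ndarray, level: float = 0.95):
        """95% confidence band of the mean response at ``x_new``."""
        x_new = np.asarray(x_new, dtype=float)
        xbar = float(np.mean(self.x))
        sxx = float(np.sum((self.x - xbar) ** 2))
        fit = self.intercept + self.slope * x_new
        se = self.residual_se * np.sqrt(1.0 / self.n + (x_new - xbar) ** 2 / sxx)
        t = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return fit - t * se, fit + t * se


def ln_transform(values: np.ndarray, offset: float = LN_OFFSET) -> np.ndarray:
    """Natural log with a fixed offset so zero measurements stay finite."""
    return np.log(np.asarray(values, dtype=float) + offset)


def fit_regression(x, y, transform: str = "raw", ln_offset: float = LN_OFFSET) -> RegressionFit:
    """OLS of y on x, optionally after ln-transforming both variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal lengths")
    if x.size < 3:
        raise ParameterError("regression needs at least 3 points")
    if transform == "ln":
        x, y = ln_transform(x, ln_offset), ln_transform(y, ln_offset)
    elif transform != "raw":
        raise ParameterError("transform must be 'raw' or 'ln'")
    if np.std(x) == 0:
        raise ParameterError("x has zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = x.size - 2
    residual_se = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        transform=transform,
        x=x,
        y=y,
        residual_se=residual_se,
        n=int(x.size),
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    x_values: np.ndarray  # reference measurements (X axis)
    differences: np.ndarray  # test - reference
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    multiplier: float
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)


def bland_altman(reference, test, multiplier: float = 2.0, bins: int = 12) -> BlandAltmanResult:
    """Bland-Altman agreement with the reference method on the X axis.

    Differences are test - reference; the limits of agreement are
    mean +/- multiplier * SD with the sample SD (n-1 denominator).  Plotting
    against the reference rather than the pairwise mean is the appropriate
    choice when one method is a criterion standard (Krouwer's argument).
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValidationError("reference and test must have equal lengths")
    if ref.size < 2:
        raise ParameterError("Bland-Altman needs at least 2 paired measurements")
    d = tst - ref
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    counts, edges = np.histogram(d, bins=bins)
    return BlandAltmanResult(
        x_values=ref,
        differences=d,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - multiplier * sd_d,
        loa_high=mean_d + multiplier * sd_d,
        multiplier=float(multiplier),
        histogram=(counts, edges),
    )


def format_p(p: float) -> str:
    """Report very small p-values as '<0.001', never as a literal zero."""
    if np.isnan(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def pairs_table(comparisons: list[PairedComparison]) -> pd.DataFrame:
    """Paired-comparison table: mean and SD of differences, Z, p."""
    return pd.DataFrame(
        {
            "pair": [c.name for c in comparisons],
            "mean_difference": [c.mean_difference for c in comparisons],
            "sd_difference": [c.sd_difference for c in comparisons],
            "z": [c.z_statistic for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "p_display": [format_p(c.p_value) for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    ).set_index("pair")
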