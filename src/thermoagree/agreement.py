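"""Method-comparison statistics for paired temperature measurements.

The battery mirrors standard practice for validating a new thermometer
against a reference: a paired t-test on the differences, Bland-Altman bias
and 95 % limits of agreement (LoA) with their confidence intervals, the
intraclass correlation coefficient ICC(3,1) — two-way mixed effects,
single measure, consistency — with its F-distribution confidence interval
and Cicchetti reliability label, and the fraction of pairs within a
clinically acceptable corridor (±0.5 °C by convention).

Conventions fixed here: differences are double-sensor minus reference; the
LoA multiplier is 1.96 (not a t-quantile), making the identities
``midpoint(LoA) == bias`` and ``width(LoA) == 3.92·SD`` exact; consistency
ICC ignores a constant offset between methods by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .pairing import PairedDataset

__all__ = [
    "AgreementReport",
    "paired_t_test",
    "bland_altman",
    "BlandAltmanResult",
    "icc_consistency",
    "classify_icc",
    "pct_within_threshold",
    "build_report",
    "bland_altman_plot_data",
]

LOA_Z = 1.96

ICC_CLASS_BOUNDS = ((0.4, "poor"), (0.6, "moderate"), (0.75, "good"))


def paired_t_test(diffs) -> tuple[float, float, int]:
    """One-sample t-test of the paired differences against zero.

    Returns ``(t, p, n)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` (sample SD,
    n-1 denominator) and a two-sided p-value on n-1 degrees of freedom.
    Zero spread is rejected outright — a t statistic is undefined there, and
    a zero bias is the caller's separate check.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2, got {n}")
    sd = d.std(ddof=1)
    # all-equal inputs have zero spread even when rounding leaves sd != 0
    if sd == 0 or np.all(d == d[0]):
        raise ValueError("paired t-test undefined for zero-variance differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), int(n)


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    sd: float
    bias_ci: tuple[float, float]
    loa_low: float
    loa_high: float
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]


def bland_altman(diffs, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman bias, SD and 95 % limits of agreement with CIs.

    LoA = bias ± 1.96·SD. The bias CI uses the exact t interval; each LoA
    bound's CI uses the Bland & Altman large-sample standard error
    ``SD·sqrt(1/n + 1.96²/(2(n-1)))``.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError(f"Bland-Altman needs n >= 3, got {n}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tq = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    half_bias = tq * sd / math.sqrt(n)
    se_loa = sd * math.sqrt(1.0 / n + LOA_Z**2 / (2.0 * (n - 1)))
    loa_low = bias - LOA_Z * sd
    loa_high = bias + LOA_Z * sd
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd=sd,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_low=loa_low,
        loa_high=loa_high,
        loa_low_ci=(loa_low - tq * se_loa, loa_low + tq * se_loa),
        loa_high_ci=(loa_high - tq * se_loa, loa_high + tq * se_loa),
    )


def _two_way_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(MSB, MSC, MSE) of the n-subject x 2-rater two-way layout."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssb - ssc
    msb = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(msb), float(msc), float(mse)


def icc_consistency(
    x, y, alpha: float = 0.05, absolute: bool = False
) -> tuple[float, tuple[float, float]]:
    """Single-measure two-way mixed ICC for two aligned measurement lists.

    The default is the consistency form, ICC(3,1) in Shrout-Fleiss
    notation: ``(MSB - MSE) / (MSB + (k-1)·MSE)`` with k = 2, which is
    insensitive to a constant shift between the two methods. The 95 % CI
    comes from the F method: with ``F = MSB/MSE`` on ``(n-1, n-1)`` degrees
    of freedom, the bounds are ``(F/F_u - 1)/(F/F_u + k - 1)`` and
    ``(F·F_l - 1)/(F·F_l + k - 1)``.

    ``absolute=True`` switches to the absolute-agreement single-measure
    form ICC(A,1) (McGraw & Wong), provided for sensitivity analysis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    k = 2
    if n < 5:
        raise ValueError(f"ICC needs n >= 5 subjects, got {n}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("ICC requires finite values with no missing cells")
    msb, msc, mse = _two_way_mean_squares(x, y)
    if msb + mse == 0:
        raise ValueError("ICC undefined: no variance in the data (all values equal)")

    if not absolute:
        icc = (msb - mse) / (msb + (k - 1) * mse)
        if mse == 0:
            return 1.0, (1.0, 1.0)
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f = msb / mse
        f_upper = stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
        f_lower = stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
        lo = (f / f_upper - 1.0) / (f / f_upper + k - 1.0)
        hi = (f * f_lower - 1.0) / (f * f_lower + k - 1.0)
        return float(icc), (float(lo), float(hi))

    # ICC(A,1): absolute agreement, rater variance enters the denominator
    icc = (msb - mse) / (msb + (k - 1) * mse + k / n * (msc - mse))
    if mse == 0 and msc == mse:
        return 1.0, (1.0, 1.0)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_star = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_star2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = (
        n * (msb - f_star * mse)
        / (f_star * (k * msc + (k * n - k - n) * mse) + n * msb)
    )
    hi = (
        n * (f_star2 * msb - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_star2 * msb)
    )
    return float(icc), (float(lo), float(hi))


def classify_icc(icc: float) -> str:
    """Cicchetti reliability label for an ICC value.

    Half-open bins cover the published cutoffs without gaps:
    [0, 0.4) poor, [0.4, 0.6) moderate, [0.6, 0.75) good, >= 0.75 excellent.
    Negative ICCs (worse than chance) fall in "poor".
    """
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    label = "excellent"
    for bound, name in reversed(ICC_CLASS_BOUNDS):
        if icc < bound:
            label = name
    return label


def pct_within_threshold(diffs, threshold: float = 0.5) -> float:
    """Percentage of differences with |d| <= threshold (boundary inclusive)."""
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("pct_within_threshold needs at least one difference")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return float(100.0 * np.mean(np.abs(d) <= threshold))


@dataclass
class AgreementReport:
    """Full agreement summary for one analysis run.

    Degenerate inputs (zero-variance differences) leave ``t_stat`` and
    ``p_value`` as NaN with an explanatory entry in ``notes`` instead of
    aborting the report.
    """

    n: int
    bias: float
    sd: float
    bias_ci: tuple[float, float]
    loa_low: float
    loa_high: float
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    t_stat: float
    p_value: float
    icc: float
    icc_ci: tuple[float, float]
    icc_class: str
    pct_within: float
    threshold: float
    n_candidate_pairs: int = 0
    n_artifacts: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("bias_ci", "loa_low_ci", "loa_high_ci", "icc_ci"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        d = dict(d)
        for key in ("bias_ci", "loa_low_ci", "loa_high_ci", "icc_ci"):
            d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "AgreementReport":
        return cls.from_dict(json.loads(s))

    def to_text(self) -> str:
        """Human-readable key-value summary, rounded for display only."""

        def r2(v: float) -> str:
            return "nan" if not np.isfinite(v) else f"{v:.2f}"

        def sig2(p: float) -> str:
            if not np.isfinite(p):
                return "nan"
            return f"{p:.2g}" if p >= 0.001 else "<0.001"

        lines = [
            f"n_pairs: {self.n}",
            f"candidate_pairs: {self.n_candidate_pairs}",
            f"artifacts_removed: {self.n_artifacts}",
            f"bias_c: {r2(self.bias)} (95% CI {r2(self.bias_ci[0])} to {r2(self.bias_ci[1])})",
            f"sd_c: {r2(self.sd)}",
            f"loa_c: {self.loa_low:.3f}; {self.loa_high:.3f}",
            f"loa_low_ci: {self.loa_low_ci[0]:.3f} to {self.loa_low_ci[1]:.3f}",
            f"loa_high_ci: {self.loa_high_ci[0]:.3f} to {self.loa_high_ci[1]:.3f}",
            f"t: {r2(self.t_stat)}",
            f"p: {sig2(self.p_value)}",
            f"icc: {r2(self.icc)} (95% CI {r2(self.icc_ci[0])} to {r2(self.icc_ci[1])})",
            f"icc_class: {self.icc_class}",
            f"pct_within_{self.threshold:g}c: {self.pct_within:.1f}",
        ]
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def build_report(
    filtered: PairedDataset,
    threshold: float = 0.5,
    alpha: float = 0.05,
    icc_absolute: bool = False,
) -> AgreementReport:
    """Aggregate the full statistical battery over the retained pairs.

    Expects a dataset that has been through the artifact filter; no
    rounding happens here — display rounding lives in ``to_text``.
    """
    if not filtered.filtered:
        raise ValueError("build_report expects an artifact-filtered dataset")
    retained = filtered.retained
    diffs = retained["diff"].to_numpy()
    notes: list[str] = []

    ba = bland_altman(diffs, alpha=alpha)
    if ba.sd == 0 or np.all(diffs == diffs[0]):
        t_stat, p_value = float("nan"), float("nan")
        notes.append("zero-variance differences: paired t statistic undefined")
    else:
        t_stat, p_value, _ = paired_t_test(diffs)
    icc, icc_ci = icc_consistency(
        retained["ds_core"].to_numpy(),
        retained["ref"].to_numpy(),
        alpha=alpha,
        absolute=icc_absolute,
    )
    return AgreementReport(
        n=ba.n,
        bias=ba.bias,
        sd=ba.sd,
        bias_ci=ba.bias_ci,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        loa_low_ci=ba.loa_low_ci,
        loa_high_ci=ba.loa_high_ci,
        t_stat=t_stat,
        p_value=p_value,
        icc=icc,
        icc_ci=icc_ci,
        icc_class=classify_icc(icc),
        pct_within=pct_within_threshold(diffs, threshold),
        threshold=threshold,
        n_candidate_pairs=filtered.n_total,
        n_artifacts=filtered.n_artifact,
        notes=notes,
    )


def bland_altman_plot_data(filtered: PairedDataset, report: AgreementReport):
    """Points and reference lines for an external Bland-Altman plot.

    Returns ``(points, lines)``: a DataFrame of (pair mean, difference) per
    retained pair, and a dict with the bias and both LoA levels.
    """
    retained = filtered.retained
    points = (
        retained.assign(mean=(retained["ds_core"] + retained["ref"]) / 2.0)
        .loc[:, ["mean", "diff"]]
        .reset_index(drop=True)
    )
    lines = {
        "bias": report.bias,
        "loa_low": report.loa_low,
        "loa_high": report.loa_high,
    }
    return points, lines
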