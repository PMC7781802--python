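"""Method-comparison agreement panel for paired joint-angle series.

For each joint the panel reports, over the paired differences
d_t = candidate_t − reference_t:

* bias (mean difference), its SD, SE and 95% CI (normal 1.96 multiplier);
* MAE, MAD, RMSE and sMAPE error magnitudes;
* ICC(A,2): the two-way ANOVA intraclass correlation for absolute agreement
  of k = 2 averaged measurements (McGraw & Wong nomenclature), with its
  exact F-based 95% confidence interval;
* the Fleiss interpretation band of the ICC (poor / fair-to-good /
  excellent);
* box-plot summaries of the differences with 1.5 × IQR whiskers.

MAD is reported as the median absolute deviation about the median of the
differences (a robust scale); the mean absolute deviation about the mean is
available via ``mad_kind="mean"``.

sMAPE uses the half-sum denominator, ``100 · mean(|c−r| / ((|c|+|r|)/2))``,
bounded at 200%, with 0/0 summands defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .errors import InsufficientDataError, UndefinedStatisticError
from .preprocess import PairedAngleSeries

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AgreementReport:
    """One panel row: all agreement statistics for one joint."""

    joint_name: str
    bias: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    mae: float
    mad: float
    rmse: float
    smape: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_class: str
    n: int


@dataclass
class BoxplotStats:
    """Five-number box-plot summary with 1.5 × IQR whiskers."""

    joint_name: str
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(repr=False)


def bias_stats(pairs: PairedAngleSeries) -> tuple[float, float, float, float, float]:
    """Mean difference (bias), its SD, SE, and normal 95% CI bounds.

    SD uses the n−1 denominator; CI = bias ± 1.96 · SD/√n.
    """
    d = pairs.differences
    n = d.size
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 pairs, got {n}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    return bias, sd, se, bias - Z95 * se, bias + Z95 * se


def error_metrics(
    pairs: PairedAngleSeries, mad_kind: str = "median"
) -> tuple[float, float, float, float]:
    """(MAE, MAD, RMSE, sMAPE) of the paired differences.

    ``mad_kind="median"`` (default) gives the median absolute deviation about
    the median of the differences; ``"mean"`` gives the mean absolute
    deviation about the mean.  sMAPE is in percent, bounded at 200.
    """
    c, r = pairs.candidate, pairs.reference
    d = pairs.differences
    mae = float(np.abs(d).mean())
    if mad_kind == "median":
        mad = float(np.median(np.abs(d - np.median(d))))
    elif mad_kind == "mean":
        mad = float(np.abs(d - d.mean()).mean())
    else:
        raise ValueError(f"mad_kind must be 'median' or 'mean', got {mad_kind!r}")
    rmse = float(np.sqrt((d**2).mean()))
    denom = (np.abs(c) + np.abs(r)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        summand = np.abs(c - r) / denom
    summand = np.where(denom == 0, 0.0, summand)  # 0/0 defined as 0
    smape = float(100.0 * summand.mean())
    return mae, mad, rmse, smape


def rmse_from_moments(bias: float, sd: float, n: int) -> float:
    """RMSE reconstructed from the mean, sample SD and count of differences.

    RMSE² = bias² + SD²·(n−1)/n exactly, since the sample SD uses the n−1
    denominator while the RMSE averages over n.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(np.sqrt(bias**2 + sd**2 * (n - 1) / n))


def _anova_two_way(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way single-observation ANOVA on an n×k table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0)


def icc_a2(
    pairs_or_matrix: PairedAngleSeries | np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """ICC(A,2): two-way, absolute-agreement, average-measures ICC for k = 2.

    Accepts a :class:`~poseagree.preprocess.PairedAngleSeries` or an n×2
    matrix (rows = paired frames, columns = the two raters).  Returns
    ``(icc, ci_low, ci_high)`` with the exact F-based confidence interval of
    McGraw & Wong: the single-measure interval is computed first, then
    stepped up to average measures via the Spearman–Brown relation.
    """
    if isinstance(pairs_or_matrix, PairedAngleSeries):
        x = np.column_stack(
            [pairs_or_matrix.candidate, pairs_or_matrix.reference]
        )
    else:
        x = np.asarray(pairs_or_matrix, dtype=float)
    n, k = x.shape
    if n < 3:
        raise InsufficientDataError(f"ICC needs n >= 3 rows, got {n}")
    if np.ptp(x) > 0 and (x == x[:, :1]).all():
        # identical non-constant raters: perfect agreement, exactly
        return 1.0, 1.0, 1.0

    msr, msc, mse = _anova_two_way(x)
    denom_k = msr + (msc - mse) / n
    if msr <= 1e-12 * max(1.0, abs(x).max() ** 2):
        raise UndefinedStatisticError(
            "zero between-subject variance: ICC undefined (the series carry "
            "no signal to agree on)"
        )
    if mse == 0.0 and msc == 0.0:
        # perfect agreement: both columns identical
        return 1.0, 1.0, 1.0
    icc_k = (msr - mse) / denom_k

    # Single-measure ICC(A,1) and its F-based CI (Satterthwaite df), then
    # step-up.  r is the A,1 point estimate.
    r = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if np.isinf(a):
        v = (n - 1) * (k - 1)
    else:
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
    f_u = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
    l1 = n * (msr - f_u * mse) / (
        f_u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    u1 = n * (f_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_l * msr
    )
    # Spearman-Brown step-up from single to average measures
    lo = l1 * k / (1 + (k - 1) * l1)
    hi = u1 * k / (1 + (k - 1) * u1)
    lo, hi = min(lo, hi), max(lo, hi)
    lo, hi = max(lo, -1.0), min(hi, 1.0)
    # at very small n the F-interval denominators can flip sign and the
    # formula stops bracketing the estimate; fall back to the uninformative
    # bound rather than report an inverted interval
    if lo > icc_k:
        lo = -1.0
    if hi < icc_k:
        hi = 1.0
    return float(icc_k), float(lo), float(hi)


def classify_icc(icc: float) -> str:
    """Fleiss interpretation band: poor < 0.40 ≤ fair-to-good < 0.75 ≤ excellent."""
    if not -1.0 <= icc <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {icc}")
    if icc < 0.40:
        return "poor"
    if icc < 0.75:
        return "fair-to-good"
    return "excellent"


def agreement_report(
    pairs: PairedAngleSeries, mad_kind: str = "median"
) -> AgreementReport:
    """Compute the full panel row for one joint's pooled pairs."""
    bias, sd, se, lo, hi = bias_stats(pairs)
    mae, mad, rmse, smape = error_metrics(pairs, mad_kind=mad_kind)
    icc, icc_lo, icc_hi = icc_a2(pairs)
    return AgreementReport(
        joint_name=pairs.joint_name,
        bias=bias,
        sd=sd,
        se=se,
        ci_low=lo,
        ci_high=hi,
        mae=mae,
        mad=mad,
        rmse=rmse,
        smape=smape,
        icc=icc,
        icc_ci_low=icc_lo,
        icc_ci_high=icc_hi,
        icc_class=classify_icc(icc),
        n=pairs.n,
    )


def per_video_icc(
    grouped_pairs: list[PairedAngleSeries], flag_below: float = 0.75
) -> list[dict]:
    """ICC(A,2) within each (video, joint) group.

    Groups whose ICC falls below ``flag_below`` are flagged; a group that
    fails (e.g. zero variance) is reported with an ``error`` field rather
    than aborting the remaining groups.
    """
    rows = []
    for p in grouped_pairs:
        row: dict = {"video_id": p.video_id, "joint_name": p.joint_name, "n": p.n}
        try:
            icc, lo, hi = icc_a2(p)
            row.update(
                icc=icc,
                icc_ci_low=lo,
                icc_ci_high=hi,
                icc_class=classify_icc(icc),
                flagged=bool(icc < flag_below),
            )
        except (InsufficientDataError, UndefinedStatisticError) as exc:
            row.update(icc=np.nan, error=str(exc), flagged=True)
        rows.append(row)
    return rows


def boxplot_stats(
    differences: np.ndarray, joint_name: str = ""
) -> BoxplotStats:
    """Box-plot summary with whiskers at 1.5 × IQR beyond the quartiles.

    Quartiles use the linear-interpolation quantile rule.  Whiskers are
    clipped to the most extreme observations inside the 1.5 × IQR fences;
    points beyond them are returned as outliers.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise InsufficientDataError("empty difference vector")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = d[(d >= lo_fence) & (d <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = np.sort(d[(d < lo_fence) | (d > hi_fence)])
    return BoxplotStats(
        joint_name=joint_name,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )
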