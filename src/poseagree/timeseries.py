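"""Stationarity and temporal-lag diagnostics for paired angle series.

Two diagnostics support the agreement panel:

* :func:`adf_test` — the augmented Dickey-Fuller unit-root test (constant
  term, no trend; lag order chosen by AIC up to ⌊12·(n/100)^0.25⌋).
  Rejection at α = 0.05 indicates a stationary series, the prerequisite for
  interpreting cross-correlations.
* :func:`cross_correlation` — the normalised cross-covariance over integer
  lags.  A peak away from lag 0 diagnoses a temporal shift between the two
  measurement systems.

Lag-direction convention: a **positive** lag means the candidate lags
(trails) the reference, i.e. candidate_t best matches reference_{t−lag}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .angles import AngleSeries
from .errors import InsufficientDataError, UndefinedStatisticError
from .preprocess import PairedAngleSeries

ADF_ALPHA = 0.05


@dataclass
class AdfResult:
    """Augmented Dickey-Fuller outcome for one series."""

    joint_name: str
    statistic: float
    p_value: float
    stationary: bool  # p < 0.05: unit root rejected
    n_lags: int


@dataclass
class CcfResult:
    """Cross-correlation function over integer lags for one joint."""

    joint_name: str
    lags: np.ndarray = field(repr=False)
    ccf: np.ndarray = field(repr=False)
    best_lag: int
    best_corr: float
    conf_bound: float  # ±1.96/√n significance band


def default_max_lag(n: int) -> int:
    """Default cross-correlation window: min(10·log10(n), n/4), rounded."""
    return max(1, int(round(min(10 * np.log10(n), n / 4))))


def adf_test(
    series: AngleSeries | np.ndarray, joint_name: str | None = None
) -> AdfResult:
    """Augmented Dickey-Fuller test with constant term and AIC lag choice.

    ``stationary`` is True when the unit-root null is rejected at α = 0.05.
    A constant series has a degenerate test regression and raises.
    """
    if isinstance(series, AngleSeries):
        x = series.values
        joint_name = joint_name or series.joint_name
    else:
        x = np.asarray(series, dtype=float)
        joint_name = joint_name or ""
    x = x[np.isfinite(x)]
    n = x.size
    if n < 20:
        raise InsufficientDataError(f"ADF needs at least 20 points, got {n}")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError(
            f"{joint_name}: constant series, ADF regression degenerate"
        )
    maxlag = int(np.floor(12 * (n / 100.0) ** 0.25))
    maxlag = min(maxlag, (n - 1) // 2 - 1)
    stat, pvalue, usedlag, *_ = adfuller(
        x, maxlag=maxlag, regression="c", autolag="AIC"
    )
    return AdfResult(
        joint_name=joint_name,
        statistic=float(stat),
        p_value=float(pvalue),
        stationary=bool(pvalue < ADF_ALPHA),
        n_lags=int(usedlag),
    )


def cross_correlation(
    pairs: PairedAngleSeries, max_lag: int | None = None
) -> CcfResult:
    """Normalised cross-correlation of candidate vs reference over ±max_lag.

    Both series are mean-centred; the normalisation uses the full-series
    n-denominator standard deviations, so ccf(0) equals the Pearson
    correlation of the pairs.  ``best_lag`` is the lag of maximum
    correlation; positive means the candidate trails the reference.
    """
    c = pairs.candidate - pairs.candidate.mean()
    r = pairs.reference - pairs.reference.mean()
    n = c.size
    if max_lag is None:
        max_lag = default_max_lag(n)
    if not 1 <= max_lag < n:
        raise InsufficientDataError(
            f"need n > max_lag >= 1, got n={n}, max_lag={max_lag}"
        )
    sc = np.sqrt((c**2).mean())
    sr = np.sqrt((r**2).mean())
    if sc == 0 or sr == 0:
        raise UndefinedStatisticError(
            f"{pairs.joint_name}: zero-variance series, correlation undefined"
        )
    lags = np.arange(-max_lag, max_lag + 1)
    ccf = np.empty(lags.size)
    for i, h in enumerate(lags):
        if h >= 0:
            s = float(np.dot(c[h:], r[: n - h]))
        else:
            s = float(np.dot(c[: n + h], r[-h:]))
        ccf[i] = s / (n * sc * sr)
    best = int(np.argmax(ccf))
    return CcfResult(
        joint_name=pairs.joint_name,
        lags=lags,
        ccf=ccf,
        best_lag=int(lags[best]),
        best_corr=float(ccf[best]),
        conf_bound=float(1.96 / np.sqrt(n)),
    )
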