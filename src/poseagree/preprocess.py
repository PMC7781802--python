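"""Smoothing, imputation, and frame alignment of angle series.

The preparation pipeline is smooth → impute → pair:

1. :func:`bartlett_smooth` — normalised triangular (Bartlett) window
   convolution, default length 11, reflect padding so output length equals
   input length.  Missing frames are linearly bridged for the convolution
   only; the missingness mask is preserved on output.
2. :func:`impute_moving_average` — centred simple-moving-average fill of
   missing values (default window 5); runs longer than the window are
   bridged by linear interpolation, leading/trailing gaps take the nearest
   valid value.
3. :func:`pair_series` — frame-aligns a candidate and a reference series.
   When frame rates differ, the higher-rate series is linearly resampled
   onto the lower-rate series' frame times, restricted to the overlapping
   time range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import AngleSeries
from .errors import PairingError, ParameterError, UnimputableError


@dataclass
class PairedAngleSeries:
    """Frame-aligned candidate/reference angle pairs for one joint.

    The per-frame difference ``candidate - reference`` is the unit of all
    downstream agreement statistics.
    """

    video_id: str
    joint_name: str
    candidate: np.ndarray  # degrees
    reference: np.ndarray  # degrees
    fps: float  # rate of the pairing grid

    def __post_init__(self) -> None:
        if self.candidate.shape != self.reference.shape:
            raise PairingError("candidate/reference length mismatch")
        if self.n < 2:
            raise PairingError(f"need at least 2 pairs, got {self.n}")

    @property
    def n(self) -> int:
        return self.candidate.size

    @property
    def differences(self) -> np.ndarray:
        return self.candidate - self.reference


def _bartlett_weights(window: int) -> np.ndarray:
    """Normalised triangular weights; endpoints are zero (Bartlett taper)."""
    w = np.bartlett(window)
    return w / w.sum()


def _bridge_missing(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Linearly interpolate across missing entries (nearest value at edges)."""
    if not missing.any():
        return values
    if missing.all():
        raise UnimputableError("series is entirely missing")
    x = np.arange(values.size, dtype=float)
    filled = values.copy()
    filled[missing] = np.interp(x[missing], x[~missing], values[~missing])
    return filled


def bartlett_smooth(series: AngleSeries, window: int = 11) -> AngleSeries:
    """Smooth an angle series with a normalised Bartlett (triangular) window.

    ``window`` must be odd, at least 3, and no longer than the series.  The
    ends are reflect-padded so the output has the input's length, and a
    constant series passes through unchanged (the weights sum to 1).  Frames
    flagged missing stay missing on output.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if window > series.n_frames:
        raise ParameterError(
            f"window {window} exceeds series length {series.n_frames}"
        )
    w = _bartlett_weights(window)
    half = window // 2
    x = _bridge_missing(series.values, series.missing)
    padded = np.pad(x, half, mode="reflect")
    smoothed = np.convolve(padded, w, mode="valid")
    out = np.where(series.missing, np.nan, smoothed)
    return series.copy_with(out, series.missing.copy())


def impute_moving_average(series: AngleSeries, window: int = 5) -> AngleSeries:
    """Fill missing values with a centred simple moving average.

    Each missing value becomes the mean of the non-missing values inside the
    centred window.  Where a missing run is too long for any window to reach
    a valid neighbour, linear interpolation between the nearest valid values
    is used instead; leading/trailing gaps take the nearest valid value.
    Non-missing values are never altered.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if series.missing.all():
        raise UnimputableError(
            f"{series.video_id}/{series.joint_name}: all frames missing"
        )
    values = series.values.copy()
    missing = series.missing
    n = values.size
    half = window // 2
    bridge = _bridge_missing(series.values, missing)
    # contiguous missing runs: short runs get the windowed mean, runs longer
    # than the window (and edge runs with no valid neighbour in reach) get
    # the linear bridge / nearest-value fill
    idx = np.flatnonzero(missing)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1) if idx.size else []
    for run in runs:
        if run.size > window:
            values[run] = bridge[run]
            continue
        for i in run:
            lo, hi = max(0, i - half), min(n, i + half + 1)
            neighb = values[lo:hi][~missing[lo:hi]]
            values[i] = neighb.mean() if neighb.size else bridge[i]
    return series.copy_with(values, np.zeros(n, dtype=bool))


def pair_series(
    candidate: AngleSeries, reference: AngleSeries
) -> PairedAngleSeries:
    """Frame-align candidate and reference series into analysis pairs.

    Both series must be imputed (no missing values), describe the same video
    and joint.  Equal-rate series pair on their common frame indices; with
    unequal rates the higher-rate series is linearly resampled in time onto
    the lower-rate series' frame times, restricted to the overlap.
    """
    if candidate.video_id != reference.video_id:
        raise PairingError(
            f"video mismatch: {candidate.video_id!r} vs {reference.video_id!r}"
        )
    if candidate.joint_name != reference.joint_name:
        raise PairingError(
            f"joint mismatch: {candidate.joint_name!r} vs {reference.joint_name!r}"
        )
    if candidate.missing.any() or reference.missing.any():
        raise PairingError("series must be imputed before pairing")

    tc, tr = candidate.times, reference.times
    lo = max(tc[0], tr[0])
    hi = min(tc[-1], tr[-1])
    if hi < lo:
        raise PairingError(
            f"{candidate.video_id}/{candidate.joint_name}: "
            "non-overlapping time ranges"
        )

    if candidate.fps >= reference.fps:
        target, source = reference, candidate
        swap = False
    else:
        target, source = candidate, reference
        swap = True
    keep = (target.times >= lo) & (target.times <= hi)
    t = target.times[keep]
    resampled = np.interp(t, source.times, source.values)
    kept = target.values[keep]
    cand, ref = (resampled, kept) if not swap else (kept, resampled)
    return PairedAngleSeries(
        video_id=candidate.video_id,
        joint_name=candidate.joint_name,
        candidate=cand,
        reference=ref,
        fps=target.fps,
    )
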