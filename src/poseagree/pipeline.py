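"""End-to-end validation pipeline and tabular report rendering.

``run_validation`` executes the whole chain — read → extract angles →
Bartlett smooth → impute → pair → agreement panel (+ per-video ICC) →
box-plot summaries → ADF stationarity → cross-correlation lag scan — and
``write_report_bundle`` emits every table as CSV/JSON plus a structured run
log.  ``render_table1`` formats the pooled panel at the conventional printed
precision (2 decimals, 3 for the ICC, half-up rounding).

By default the Bartlett filter is applied to both the candidate and the
reference series so the two systems are compared like with like (and a
noise-free candidate agrees with its reference exactly); set
``smooth_target="candidate"`` to filter only the candidate stream, as a
smoothing step embedded in the candidate estimator would.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    AgreementReport,
    BoxplotStats,
    agreement_report,
    boxplot_stats,
    per_video_icc,
)
from .angles import DEFAULT_TRIPLETS, JointTripletDef, extract_angle_series
from .errors import PoseagreeError
from .io import KeypointStream, read_body25_json, read_keypoints_csv, read_panoptic_pose
from .layouts import LAYOUTS
from .preprocess import (
    PairedAngleSeries,
    bartlett_smooth,
    impute_moving_average,
    pair_series,
)
from .synthetic import MotionSpec, NoiseSpec, apply_angle_bias, generate_paired_dataset
from .timeseries import adf_test, cross_correlation, default_max_lag


@dataclass
class PipelineConfig:
    """All knobs of one validation run."""

    candidate_path: str = ""
    candidate_format: str = "body25"  # body25 | panoptic | csv
    reference_path: str = ""
    reference_format: str = "panoptic"
    candidate_layout: str = "body25"  # layout name for csv inputs
    reference_layout: str = "panoptic15"
    candidate_fps: float = 30.0
    reference_fps: float = 30.0
    smooth_window: int = 11
    smooth_target: str = "both"  # both | candidate | none
    impute_window: int = 5
    max_lag: int | None = None
    icc_decimals: int = 3
    per_video: bool = True
    out_dir: str = "poseagree_out"
    seed: int = 0

    def validate(self) -> None:
        for w in (self.smooth_window, self.impute_window):
            if w % 2 == 0:
                raise PoseagreeError(f"window sizes must be odd, got {w}")
        if self.smooth_target not in ("both", "candidate", "none"):
            raise PoseagreeError(
                f"smooth_target must be both|candidate|none, got "
                f"{self.smooth_target!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class ReportBundle:
    """Everything one validation run computes."""

    reports: list[AgreementReport]
    pooled_pairs: dict[str, PairedAngleSeries]
    per_video: list[dict]
    boxplots: list[BoxplotStats]
    ccf: list  # CcfResult per joint (pooled per-video consensus)
    adf: list[dict]  # per (video, joint, series) ADF rows
    log: list[dict]
    errors: list[dict]


def _read_streams(
    path: str, fmt: str, layout_name: str, fps: float
) -> list[KeypointStream]:
    if fmt == "body25":
        return [read_body25_json(path, fps=fps)]
    if fmt == "panoptic":
        return [read_panoptic_pose(path, fps=fps)]
    if fmt == "csv":
        return read_keypoints_csv(path, LAYOUTS[layout_name], fps=fps)
    raise PoseagreeError(f"unknown format {fmt!r}")


def _prepare(
    stream: KeypointStream,
    config: PipelineConfig,
    smooth: bool,
    defs: tuple[JointTripletDef, ...],
    log: list[dict],
) -> dict[str, "object"]:
    """Extract, optionally smooth, and impute all joint series of a stream."""
    series = extract_angle_series(stream, defs)
    out = {}
    for s in series:
        n_missing = int(s.missing.sum())
        if smooth:
            s = bartlett_smooth(s, config.smooth_window)
        s = impute_moving_average(s, config.impute_window)
        log.append(
            {
                "stage": "prepare",
                "video_id": s.video_id,
                "joint": s.joint_name,
                "frames": s.n_frames,
                "imputed": n_missing,
            }
        )
        out[s.joint_name] = s
    return out


def _pool_pairs(per_video_pairs: list[PairedAngleSeries]) -> PairedAngleSeries:
    first = per_video_pairs[0]
    return PairedAngleSeries(
        video_id="__pooled__",
        joint_name=first.joint_name,
        candidate=np.concatenate([p.candidate for p in per_video_pairs]),
        reference=np.concatenate([p.reference for p in per_video_pairs]),
        fps=first.fps,
    )


def run_validation_streams(
    candidate_streams: list[KeypointStream],
    reference_streams: list[KeypointStream],
    config: PipelineConfig | None = None,
    defs: tuple[JointTripletDef, ...] = DEFAULT_TRIPLETS,
    candidate_angle_bias: dict[str, float] | None = None,
) -> ReportBundle:
    """Run the full pipeline on already-loaded streams.

    Streams pair positionally after sorting by video_id within each list
    (candidate and reference video ids may differ, as they come from
    different systems).  ``candidate_angle_bias`` applies a per-joint offset
    to candidate angle series after extraction; the synthetic study uses it
    to inject a known bias.
    """
    config = config or PipelineConfig()
    config.validate()
    if len(candidate_streams) != len(reference_streams):
        raise PoseagreeError(
            f"{len(candidate_streams)} candidate vs "
            f"{len(reference_streams)} reference videos"
        )
    log: list[dict] = []
    errors: list[dict] = []
    joint_pairs: dict[str, list[PairedAngleSeries]] = {}

    cand_sorted = sorted(candidate_streams, key=lambda s: s.video_id)
    ref_sorted = sorted(reference_streams, key=lambda s: s.video_id)
    for cand, ref in zip(cand_sorted, ref_sorted):
        smooth_c = config.smooth_target in ("both", "candidate")
        smooth_r = config.smooth_target == "both"
        try:
            cand_series = _prepare(cand, config, smooth_c, defs, log)
            ref_series = _prepare(ref, config, smooth_r, defs, log)
        except PoseagreeError as exc:
            errors.append({"video_id": cand.video_id, "error": str(exc)})
            continue
        for joint, cs in cand_series.items():
            if candidate_angle_bias and joint in candidate_angle_bias:
                cs = apply_angle_bias(cs, candidate_angle_bias[joint])
            rs = ref_series[joint]
            # the two systems label the same take differently; pair on the
            # candidate's video id
            rs = rs.copy_with(rs.values.copy(), rs.missing.copy())
            rs.video_id = cs.video_id
            try:
                pairs = pair_series(cs, rs)
            except PoseagreeError as exc:
                errors.append(
                    {"video_id": cand.video_id, "joint": joint, "error": str(exc)}
                )
                continue
            joint_pairs.setdefault(joint, []).append(pairs)
            log.append(
                {
                    "stage": "pair",
                    "video_id": cand.video_id,
                    "joint": joint,
                    "pairs": pairs.n,
                }
            )

    reports, boxplots, ccfs, adf_rows = [], [], [], []
    pooled_pairs: dict[str, PairedAngleSeries] = {}
    all_groups: list[PairedAngleSeries] = []
    for joint, plist in joint_pairs.items():
        pooled = _pool_pairs(plist)
        pooled_pairs[joint] = pooled
        all_groups.extend(plist)
        try:
            reports.append(agreement_report(pooled))
            boxplots.append(boxplot_stats(pooled.differences, joint))
        except PoseagreeError as exc:
            errors.append({"joint": joint, "error": str(exc)})
            continue
        # lag scan per video (lag is a per-recording phenomenon), majority/
        # first summary uses the pooled-consensus best lag
        max_lag = config.max_lag or default_max_lag(min(p.n for p in plist))
        per_vid_ccf = [cross_correlation(p, max_lag) for p in plist]
        best = max(per_vid_ccf, key=lambda c: c.best_corr)
        lags = per_vid_ccf[0].lags
        mean_ccf = np.mean([c.ccf for c in per_vid_ccf], axis=0)
        consensus_idx = int(np.argmax(mean_ccf))
        consensus = type(best)(
            joint_name=joint,
            lags=lags,
            ccf=mean_ccf,
            best_lag=int(lags[consensus_idx]),
            best_corr=float(mean_ccf[consensus_idx]),
            conf_bound=float(1.96 / np.sqrt(pooled.n)),
        )
        ccfs.append(consensus)
        for p in plist:
            for label, x in (
                ("candidate", p.candidate),
                ("difference", p.differences),
            ):
                try:
                    res = adf_test(x, joint_name=joint)
                    adf_rows.append(
                        {
                            "video_id": p.video_id,
                            "joint_name": joint,
                            "series": label,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "stationary": res.stationary,
                            "n_lags": res.n_lags,
                        }
                    )
                except PoseagreeError as exc:
                    adf_rows.append(
                        {
                            "video_id": p.video_id,
                            "joint_name": joint,
                            "series": label,
                            "error": str(exc),
                        }
                    )

    pv = per_video_icc(all_groups) if config.per_video else []
    return ReportBundle(
        reports=reports,
        pooled_pairs=pooled_pairs,
        per_video=pv,
        boxplots=boxplots,
        ccf=ccfs,
        adf=adf_rows,
        log=log,
        errors=errors,
    )


def run_validation(config: PipelineConfig) -> ReportBundle:
    """Read input files per the config and run the full pipeline."""
    config.validate()
    cand = _read_streams(
        config.candidate_path,
        config.candidate_format,
        config.candidate_layout,
        config.candidate_fps,
    )
    ref = _read_streams(
        config.reference_path,
        config.reference_format,
        config.reference_layout,
        config.reference_fps,
    )
    return run_validation_streams(cand, ref, config)


def run_synthetic_study(
    motion: MotionSpec | None = None,
    noise: NoiseSpec | None = None,
    config: PipelineConfig | None = None,
) -> ReportBundle:
    """Generate a paired synthetic dataset and validate it end to end."""
    motion = motion or MotionSpec()
    noise = noise or NoiseSpec()
    dataset = generate_paired_dataset(motion, noise)
    bias_map = {
        j: noise.bias_for(j)
        for j in (r.joint_name for r in _all_joint_names())
        if noise.bias_for(j) != 0.0
    }
    return run_validation_streams(
        dataset.candidate,
        dataset.reference,
        config,
        candidate_angle_bias=bias_map or None,
    )


def _all_joint_names():
    return DEFAULT_TRIPLETS


# ---------------------------------------------------------------------------
# rendering and serialization


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding at the given precision (printed convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float, decimals: int = 2) -> str:
    return f"{round_half_up(x, decimals):.{decimals}f}"


TRIPLET_LABEL = {d.joint_name: ", ".join(d.triplet) for d in DEFAULT_TRIPLETS}

JOINT_ORDER = [d.joint_name for d in DEFAULT_TRIPLETS]


def render_table1(
    reports: list[AgreementReport], icc_decimals: int = 3
) -> pd.DataFrame:
    """Format the pooled agreement panel at the printed precision.

    Columns: joint, key points used, mean difference (SD) with 95% CI, MAE,
    MAD, RMSE, sMAPE, ICC (95% CI), SE — values half-up rounded to 2
    decimals (ICC to ``icc_decimals``).
    """
    if not reports:
        raise PoseagreeError("no reports to render")
    order = {j: i for i, j in enumerate(JOINT_ORDER)}
    rows = []
    for r in sorted(reports, key=lambda r: order.get(r.joint_name, 99)):
        rows.append(
            {
                "joint": r.joint_name,
                "key_points_used": TRIPLET_LABEL.get(r.joint_name, ""),
                "difference_mean_sd_ci": (
                    f"{_fmt(r.bias)} ({_fmt(r.sd)}); "
                    f"{_fmt(r.ci_low)} to {_fmt(r.ci_high)}"
                ),
                "mae": _fmt(r.mae),
                "mad": _fmt(r.mad),
                "rmse": _fmt(r.rmse),
                "smape": _fmt(r.smape),
                "icc_ci": (
                    f"{_fmt(r.icc, icc_decimals)} "
                    f"({_fmt(r.icc_ci_low, icc_decimals)} to "
                    f"{_fmt(r.icc_ci_high, icc_decimals)})"
                ),
                "se": _fmt(r.se),
            }
        )
    return pd.DataFrame(rows)


def render_table2(ccfs: list) -> pd.DataFrame:
    """Max-correlation lag table: one row per joint."""
    order = {j: i for i, j in enumerate(JOINT_ORDER)}
    rows = [
        {
            "joint": c.joint_name,
            "lag_at_max_correlation": c.best_lag,
            "max_correlation": _fmt(c.best_corr),
        }
        for c in sorted(ccfs, key=lambda c: order.get(c.joint_name, 99))
    ]
    return pd.DataFrame(rows)


def write_report_bundle(
    bundle: ReportBundle, out_dir: str | Path, config: PipelineConfig | None = None
) -> dict[str, Path]:
    """Write every table of a run as CSV/JSON plus a structured run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rep_rows = [asdict(r) for r in bundle.reports]
    order = {j: i for i, j in enumerate(JOINT_ORDER)}
    rep_rows.sort(key=lambda r: order.get(r["joint_name"], 99))
    paths["agreement_csv"] = out / "agreement.csv"
    pd.DataFrame(rep_rows).to_csv(paths["agreement_csv"], index=False)
    paths["agreement_json"] = out / "agreement.json"
    with open(paths["agreement_json"], "w") as fh:
        json.dump(rep_rows, fh, indent=2)

    paths["table1_csv"] = out / "table1.csv"
    render_table1(bundle.reports).to_csv(paths["table1_csv"], index=False)

    if bundle.per_video:
        paths["per_video_icc_csv"] = out / "per_video_icc.csv"
        pd.DataFrame(bundle.per_video).to_csv(
            paths["per_video_icc_csv"], index=False
        )

    box_rows = []
    for b in bundle.boxplots:
        box_rows.append(
            {
                "joint_name": b.joint_name,
                "median": b.median,
                "q1": b.q1,
                "q3": b.q3,
                "iqr": b.iqr,
                "whisker_low": b.whisker_low,
                "whisker_high": b.whisker_high,
                "n_outliers": int(b.outliers.size),
                "outlier_min": float(b.outliers.min()) if b.outliers.size else "",
                "outlier_max": float(b.outliers.max()) if b.outliers.size else "",
            }
        )
    paths["boxplot_csv"] = out / "boxplot.csv"
    pd.DataFrame(box_rows).to_csv(paths["boxplot_csv"], index=False)

    ccf_rows = []
    for c in bundle.ccf:
        for lag, val in zip(c.lags, c.ccf):
            ccf_rows.append(
                {
                    "joint": c.joint_name,
                    "lag": int(lag),
                    "ccf": float(val),
                    "significant": bool(abs(val) > c.conf_bound),
                }
            )
    paths["ccf_csv"] = out / "ccf.csv"
    pd.DataFrame(ccf_rows).to_csv(paths["ccf_csv"], index=False)
    paths["table2_csv"] = out / "table2.csv"
    render_table2(bundle.ccf).to_csv(paths["table2_csv"], index=False)

    paths["adf_csv"] = out / "adf.csv"
    pd.DataFrame(bundle.adf).to_csv(paths["adf_csv"], index=False)

    paths["run_log"] = out / "run_log.json"
    with open(paths["run_log"], "w") as fh:
        json.dump(
            {
                "poseagree_version": __version__,
                "python": sys.version.split()[0],
                "config": asdict(config) if config else None,
                "log": bundle.log,
                "errors": bundle.errors,
            },
            fh,
            indent=2,
        )
    return paths
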