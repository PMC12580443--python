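"""End-to-end analysis: recordings -> pulse table -> subject summaries -> stats.

This module chains the pipeline stages (I/O and normalization, derivative
estimation, pulse detection and segmentation, per-subject aggregation,
cohort inference) and assembles the tabular/JSON reports.  The thin CLI in
:mod:`motorseg.cli` calls these functions; they are equally usable from
Python.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .kinematics import compute_derivatives
from .pulse_segmentation import QCFlag, SegmentationProfile, detect_pulses, segment_pulse
from .recording_io import ForceRecording, SubjectRecord, normalize_to_mvc
from .subject_aggregation import (
    MAX_ORDINAL,
    SubjectSummary,
    select_pulses,
    subject_seed,
    summarize_subject,
)

__all__ = [
    "AnalysisParams",
    "analyze_recording",
    "analyze_subject",
    "analyze_cohort",
    "pulse_table",
    "summary_table",
    "cohort_report",
    "STAT_MEASURES",
]

#: Subject-summary columns entering the three-group comparisons, in report
#: order, with display names.
STAT_MEASURES = {
    "med_n_seg_f90": "n_segments_to_f90",
    "med_n_seg_peak": "n_segments_to_peak",
    "med_rfd_pk": "peak_rfd",
    "med_t_f90": "time_to_f90",
    "med_t_pf": "time_to_peak_force",
    "med_first_seg_dur": "first_segment_duration",
    "med_t_rfd_pk": "time_of_peak_rfd",
    "med_rfd_pk_seg1": "peak_rfd_first_segment",
    "med_seg_of_rfd_pk": "segment_of_peak_rfd",
}


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable analysis parameters with the pipeline's defaults."""

    window_ms: float = 50.0
    rfd_threshold: float = 20.0  # %MVC/s
    min_peak: float = 10.0  # %MVC
    min_separation: float = 1.0  # s
    amplitude_lo: float = 20.0  # %MVC eligibility band
    amplitude_hi: float = 60.0
    k_pulses: int = 41
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_pulses % 2 == 0:
            warnings.warn(
                "an even pulse count allows half-integer medians of integer "
                "metrics; an odd k is recommended",
                stacklevel=2,
            )


def apply_overrides(pulses, subject_id: str, overrides: pd.DataFrame | None):
    """Attach keep/drop overrides from a manual-override table.

    The table has columns (subject_id, pulse_index, action, note) with
    action ``keep`` or ``drop``; pulse_index counts detected pulses in onset
    order.
    """
    if overrides is None:
        return pulses
    sub = overrides[overrides["subject_id"].astype(str) == subject_id]
    for _, row in sub.iterrows():
        i = int(row["pulse_index"])
        if not 0 <= i < len(pulses):
            warnings.warn(f"override for {subject_id} pulse {i} out of range", stacklevel=2)
            continue
        action = str(row["action"]).strip().lower()
        if action not in ("keep", "drop"):
            raise ValueError(f"override action must be keep/drop, got {action!r}")
        pulse = pulses[i][0] if isinstance(pulses[i], tuple) else pulses[i]
        if action == "drop":
            pulse.qc_flags.append(QCFlag("amplitude_out_of_range", override="drop"))
        else:
            pulse.qc_flags.append(QCFlag("amplitude_out_of_range", override="keep"))
    return pulses


def analyze_recording(
    rec: ForceRecording, params: AnalysisParams = AnalysisParams()
) -> list[tuple]:
    """Detect and segment every pulse in a normalized recording.

    Returns a list of (Pulse, SegmentationProfile) pairs in onset order.
    """
    deriv = compute_derivatives(rec, params.window_ms)
    pulses = detect_pulses(
        rec,
        deriv,
        rfd_threshold=params.rfd_threshold,
        min_peak=params.min_peak,
        min_separation=params.min_separation,
    )
    return [(p, segment_pulse(rec, deriv, p)) for p in pulses]


def analyze_subject(
    rec: ForceRecording,
    subject: SubjectRecord,
    params: AnalysisParams = AnalysisParams(),
    overrides: pd.DataFrame | None = None,
) -> tuple[SubjectSummary, list[tuple]]:
    """Run the per-subject pipeline: normalize, segment, select, summarize."""
    if not rec.normalized:
        if subject.mvc_force is None:
            raise ValueError(f"missing MVC for subject {subject.subject_id}")
        rec = normalize_to_mvc(rec, subject.mvc_force)
    analyzed = analyze_recording(rec, params)
    analyzed = apply_overrides(analyzed, subject.subject_id, overrides)
    seed = subject_seed(params.master_seed, subject.subject_id)
    n_eligible = sum(
        params.amplitude_lo <= p.peak_force <= params.amplitude_hi and not p.dropped
        for p, _ in analyzed
    )
    selected = select_pulses(
        analyzed,
        lo=params.amplitude_lo,
        hi=params.amplitude_hi,
        k=params.k_pulses,
        seed=seed,
        subject_id=subject.subject_id,
    )
    summary = summarize_subject(
        subject.subject_id,
        subject.group,
        selected,
        n_eligible=n_eligible,
        selection_seed=seed,
    )
    return summary, analyzed


def analyze_cohort(
    recordings: list[ForceRecording],
    subjects: list[SubjectRecord],
    params: AnalysisParams = AnalysisParams(),
    overrides: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full cohort run.

    Returns (per-pulse table, subject-summary table, stats report dict).
    Any stage failure is re-raised with the subject id attached.
    """
    by_id = {s.subject_id: s for s in subjects}
    summaries: list[SubjectSummary] = []
    pulse_frames = []
    for rec in recordings:
        sub = by_id.get(rec.subject_id)
        if sub is None:
            raise ValueError(f"no metadata row for subject {rec.subject_id}")
        try:
            summary, analyzed = analyze_subject(rec, sub, params, overrides)
        except Exception as exc:
            raise RuntimeError(f"subject {rec.subject_id}: {exc}") from exc
        summaries.append(summary)
        pulse_frames.append(pulse_table(rec, analyzed))
    pulses_df = (
        pd.concat(pulse_frames, ignore_index=True) if pulse_frames else pd.DataFrame()
    )
    summary_df = summary_table(summaries)
    report = cohort_report(summary_df, alpha=params.alpha)
    return pulses_df, summary_df, report


def pulse_table(rec: ForceRecording, analyzed: list[tuple]) -> pd.DataFrame:
    """Wide per-pulse table (one row per detected pulse)."""
    fs = rec.sample_rate
    max_seg = max((len(prof.segments) for _, prof in analyzed), default=1)
    rows = []
    for idx, (p, prof) in enumerate(analyzed):
        row = {
            "subject_id": rec.subject_id,
            "pulse_index": idx,
            "onset_time_s": p.onset_idx / fs,
            "peak_pct_mvc": p.peak_force,
            "t_pf_s": p.t_pf,
            "t_f90_s": p.t_f90,
            "n_seg_f90": prof.n_seg_f90,
            "n_seg_peak": prof.n_seg_peak,
            "rfd_pk": prof.rfd_pk,
            "t_rfd_pk_s": prof.t_rfd_pk,
            "rfd_pk_seg1": prof.rfd_pk_seg1,
            "seg_of_rfd_pk": prof.seg_of_rfd_pk,
            "first_seg_dur_s": prof.first_seg_dur,
            "qc": ";".join(f.reason for f in p.qc_flags),
            "dropped": p.dropped,
        }
        for j in range(max_seg):
            row[f"seg{j + 1}_dur_s"] = (
                prof.segment_durations[j] if j < len(prof.segment_durations) else np.nan
            )
        for j in range(max_seg - 1):
            row[f"slow{j + 1}_dur_s"] = (
                prof.slowing_durations[j] if j < len(prof.slowing_durations) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """Subject-summary table (one row per subject)."""
    rows = []
    for s in summaries:
        row = {k: v for k, v in asdict(s).items() if k not in ("seg_dur_medians", "slow_dur_medians")}
        for j in range(MAX_ORDINAL):
            row[f"seg{j + 1}_dur_med_s"] = (
                s.seg_dur_medians[j] if s.seg_dur_medians[j] is not None else np.nan
            )
            row[f"slow{j + 1}_dur_med_s"] = (
                s.slow_dur_medians[j] if s.slow_dur_medians[j] is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _measure_block(summary_df: pd.DataFrame, col: str, alpha: float) -> dict:
    order = ["PD_Seg", "PD_NoSeg", "OA"]
    groups, labels = [], []
    for g in order:
        vals = summary_df.loc[summary_df["group_final"] == g, col].dropna().to_numpy()
        if vals.size:
            groups.append(vals)
            labels.append(g)
    block: dict = {
        "descriptives": {
            lab: asdict(cs.descriptives(vals)) for lab, vals in zip(labels, groups)
        }
    }
    if len(groups) >= 2:
        omni = cs.kruskal_wallis(groups)
        block["omnibus"] = asdict(omni)
        block["pairwise"] = [asdict(pr) for pr in cs.dunn_pairwise_bonferroni(groups, labels)]
    else:
        block["omnibus"] = None
        block["pairwise"] = []
        warnings.warn(f"{col}: fewer than two groups; omnibus skipped", stacklevel=2)
    return block


def cohort_report(summary_df: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Assemble the cohort stats report from a subject-summary table.

    Blocks: segmentation prevalence among PD subjects (exact binomial vs.
    50% with Clopper-Pearson interval), one omnibus+pairwise block per force
    measure, and Friedman step-down blocks for the ordinal segment and
    slowing durations within PD_Seg.
    """
    required = {"group_raw", "group_final", *STAT_MEASURES}
    missing = required - set(summary_df.columns)
    if missing:
        raise ValueError(f"subject summary table missing columns: {sorted(missing)}")
    pd_rows = summary_df[summary_df["group_raw"] == "PD"]
    report: dict = {"alpha": alpha, "n_subjects": int(len(summary_df))}
    if len(pd_rows):
        k = int((pd_rows["group_final"] == "PD_Seg").sum())
        report["prevalence"] = asdict(cs.prevalence_test(k, len(pd_rows), p0=0.5, alpha=alpha))
    else:
        report["prevalence"] = None
    report["measures"] = {
        STAT_MEASURES[col]: _measure_block(summary_df, col, alpha)
        for col in STAT_MEASURES
    }
    report["durations"] = {}
    seg_rows = summary_df[summary_df["group_final"] == "PD_Seg"]
    for family, prefix in (("segment_durations", "seg"), ("slowing_durations", "slow")):
        cols = [c for c in summary_df.columns if c.startswith(prefix) and c.endswith("_dur_med_s")]
        # keep ordinals at least two PD_Seg subjects actually have
        cols = [c for c in cols if np.isfinite(seg_rows[c].to_numpy(dtype=float)).sum() >= 2]
        cols = sorted(cols, key=lambda c: int(c[len(prefix)])) if cols else []
        if len(cols) >= 2 and len(seg_rows) >= 2:
            mat = seg_rows[cols].to_numpy(dtype=float)
            complete = np.all(np.isfinite(mat), axis=1)
            if complete.sum() >= 2:
                fr = cs.friedman_stepdown(mat, alpha=alpha)
                report["durations"][family] = {
                    **asdict(fr),
                    "conditions": cols,
                    "descriptives": {
                        c: asdict(cs.descriptives(mat[np.isfinite(mat[:, j]), j]))
                        for j, c in enumerate(cols)
                        if np.isfinite(mat[:, j]).sum() >= 2
                    },
                }
                continue
        report["durations"][family] = None
    return report
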