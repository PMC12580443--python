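"""Per-subject pulse selection, median summaries and classification.

From each subject's detected pulses, those peaking between 20 and 60 %MVC
are eligible; 41 (an odd count, so integer-valued metrics keep integer
medians) are drawn uniformly without replacement with a per-subject seed
derived from the master seed.  Per-subject medians over the selected pulses
feed the cohort statistics, and a Parkinson's subject whose median number of
segments to F90 is >= 2 is classified as segmented (PD_Seg).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pulse_segmentation import Pulse, SegmentationProfile

__all__ = [
    "SubjectSummary",
    "subject_seed",
    "select_pulses",
    "summarize_subject",
    "classify_segmentation",
    "MAX_ORDINAL",
]

#: Number of ordinal segment/slowing positions summarized per subject.
MAX_ORDINAL = 5


@dataclass
class SubjectSummary:
    """Per-subject medians over the selected pulses plus classification."""

    subject_id: str
    group_raw: str  # OA | PD
    n_eligible: int
    n_used: int
    med_n_seg_f90: float
    med_n_seg_peak: float
    med_t_pf: float
    med_t_f90: float
    med_rfd_pk: float
    med_t_rfd_pk: float
    med_rfd_pk_seg1: float
    med_seg_of_rfd_pk: float
    med_first_seg_dur: float
    med_peak_force: float
    pct_multiseg: float  # % of used pulses with >= 2 segments to F90
    seg_dur_medians: list[float | None] = field(default_factory=list)  # ordinals 1..5
    slow_dur_medians: list[float | None] = field(default_factory=list)
    selection_seed: int = 0
    group_final: str = ""  # OA | PD_NoSeg | PD_Seg

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_multiseg <= 100.0:
            raise ValueError("pct_multiseg must lie in [0, 100]")
        if self.med_n_seg_f90 < 1:
            raise ValueError("median segments to F90 cannot be below 1")


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject seed below 2**31, independent of processing order."""
    digest = hashlib.blake2s(
        f"{master_seed}:{subject_id}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def select_pulses(
    pulses: list[tuple[Pulse, SegmentationProfile]],
    lo: float = 20.0,
    hi: float = 60.0,
    k: int = 41,
    seed: int = 0,
    subject_id: str = "",
) -> list[tuple[Pulse, SegmentationProfile]]:
    """Randomly select up to ``k`` eligible pulses.

    Eligibility: peak force in ``[lo, hi]`` %MVC and not QC-dropped.  The
    draw is keyed on pulses sorted by onset, so it is invariant to input
    ordering given the same seed and eligibility set.  With fewer than ``k``
    eligible pulses all are returned with a warning.
    """
    eligible = [
        (p, prof)
        for p, prof in pulses
        if lo <= p.peak_force <= hi and not p.dropped
    ]
    if not eligible:
        raise ValueError(
            f"no eligible pulses in [{lo}, {hi}] %MVC for subject {subject_id or '<unknown>'}"
        )
    eligible.sort(key=lambda pp: pp[0].onset_idx)
    if len(eligible) <= k:
        if len(eligible) < k:
            warnings.warn(
                f"subject {subject_id or '<unknown>'}: only {len(eligible)} eligible "
                f"pulses (< {k}); using all of them",
                stacklevel=2,
            )
        return list(eligible)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(idx)]


def _median_or_none(values: list[float]) -> float | None:
    return float(np.median(values)) if values else None


def summarize_subject(
    subject_id: str,
    group: str,
    selected: list[tuple[Pulse, SegmentationProfile]],
    n_eligible: int | None = None,
    selection_seed: int = 0,
) -> SubjectSummary:
    """Medians of every pulse metric over the selected pulses.

    Standard medians (even counts average the two central values).  Ordinal
    segment/slowing duration medians use only the pulses that possess that
    ordinal, so later ordinals summarize shrinking subsets.
    """
    if not selected:
        raise ValueError(f"no pulses selected for subject {subject_id}")
    pulses = [p for p, _ in selected]
    profs = [prof for _, prof in selected]
    med = lambda xs: float(np.median(xs))  # noqa: E731
    seg_meds, slow_meds = [], []
    for j in range(MAX_ORDINAL):
        seg_meds.append(
            _median_or_none([pr.segment_durations[j] for pr in profs if len(pr.segment_durations) > j])
        )
        slow_meds.append(
            _median_or_none([pr.slowing_durations[j] for pr in profs if len(pr.slowing_durations) > j])
        )
    n_used = len(selected)
    summary = SubjectSummary(
        subject_id=subject_id,
        group_raw=group,
        n_eligible=n_eligible if n_eligible is not None else n_used,
        n_used=n_used,
        med_n_seg_f90=med([pr.n_seg_f90 for pr in profs]),
        med_n_seg_peak=med([pr.n_seg_peak for pr in profs]),
        med_t_pf=med([p.t_pf for p in pulses]),
        med_t_f90=med([p.t_f90 for p in pulses]),
        med_rfd_pk=med([pr.rfd_pk for pr in profs]),
        med_t_rfd_pk=med([pr.t_rfd_pk for pr in profs]),
        med_rfd_pk_seg1=med([pr.rfd_pk_seg1 for pr in profs]),
        med_seg_of_rfd_pk=med([pr.seg_of_rfd_pk for pr in profs]),
        med_first_seg_dur=med([pr.first_seg_dur for pr in profs]),
        med_peak_force=med([p.peak_force for p in pulses]),
        pct_multiseg=100.0 * sum(pr.n_seg_f90 >= 2 for pr in profs) / n_used,
        seg_dur_medians=seg_meds,
        slow_dur_medians=slow_meds,
        selection_seed=selection_seed,
    )
    return classify_segmentation(summary)


def classify_segmentation(summary: SubjectSummary) -> SubjectSummary:
    """Assign the final group label.

    PD subjects with a median of two or more segments to F90 (inclusive
    threshold) are PD_Seg; remaining PD subjects are PD_NoSeg; OA subjects
    keep their label.
    """
    if summary.group_raw == "OA":
        summary.group_final = "OA"
    elif summary.med_n_seg_f90 >= 2:
        summary.group_final = "PD_Seg"
    else:
        summary.group_final = "PD_NoSeg"
    return summary
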