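"""Force-recording and subject-metadata I/O.

A recording is one session's single-channel isometric force series.  The
internal time representation is sample-indexed: sample ``i`` occurs at
``i / sample_rate`` seconds from recording start, which avoids accumulating
float error from an explicit time grid.  All downstream analysis operates on
force normalized to percent of maximal voluntary contraction (%MVC);
operations that require normalized input refuse raw-unit recordings rather
than silently rescaling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ForceRecording",
    "SubjectRecord",
    "MalformedInputError",
    "load_recording",
    "save_recording",
    "load_subject_table",
    "best_mvc",
    "normalize_to_mvc",
]

#: Generous physical bounds for a normalized force sample (%MVC).  A session
#: whose samples leave this band is treated as corrupt input.
NORMALIZED_BOUNDS = (-20.0, 150.0)

#: Relative jitter tolerated in an explicit time column before the grid is
#: declared nonuniform.
TIME_JITTER_TOL = 0.01


class MalformedInputError(ValueError):
    """Raised for nonuniform time grids, non-numeric cells and unit misuse."""


@dataclass(frozen=True)
class ForceRecording:
    """One session's force series.

    Parameters
    ----------
    subject_id : str
        Identifier linking the recording to subject metadata.
    sample_rate : float
        Sampling rate in Hz; must be positive.
    force : numpy.ndarray
        Force samples, newtons when raw and %MVC once normalized.
    mvc_force : float or None
        Maximal voluntary contraction force in newtons (set at
        normalization time).
    normalized : bool
        Whether ``force`` is expressed in %MVC.
    session_label : str
        Free-text session tag.
    """

    subject_id: str
    sample_rate: float
    force: np.ndarray
    mvc_force: float | None = None
    normalized: bool = False
    session_label: str = ""

    def __post_init__(self) -> None:
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "force", force)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if force.ndim != 1:
            raise ValueError("force must be a 1-D series")
        if not np.all(np.isfinite(force)):
            raise MalformedInputError("force series contains non-finite samples")
        if self.normalized and force.size:
            lo, hi = NORMALIZED_BOUNDS
            if force.min() < lo or force.max() > hi:
                raise MalformedInputError(
                    "normalized force outside physical bounds "
                    f"[{lo}, {hi}] %MVC: range [{force.min():.1f}, {force.max():.1f}]"
                )

    def __len__(self) -> int:
        return self.force.size

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.force.size / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.force.size) / self.sample_rate


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata carried through the pipeline, never computed.

    ``group`` is the raw recruitment group (OA or PD); the PD_Seg/PD_NoSeg
    split is assigned downstream from force data.  Covariates are optional
    clinical scores (MDS-UPDRS-III, H&Y stage, LEDD, TUG, grip, Kinesia
    ratings, years since diagnosis) and are only validated for finiteness.
    """

    subject_id: str
    group: str
    mvc_force: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("OA", "PD"):
            raise ValueError(f"group must be 'OA' or 'PD', got {self.group!r}")
        for name, value in self.covariates.items():
            if not np.isfinite(value):
                raise ValueError(f"covariate {name!r} is not finite for {self.subject_id}")
        hy = self.covariates.get("hy_stage")
        if hy is not None and not 0.0 <= hy <= 5.0:
            raise ValueError(f"H&Y stage out of range [0, 5]: {hy}")


def _read_table(path_or_buf) -> pd.DataFrame:
    """Read a comma- or tab-delimited numeric table with optional header."""
    if isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text()
    else:
        text = path_or_buf.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0].split(sep)

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if not all(_is_number(t) for t in first if t.strip()) else None
    return pd.read_csv(io.StringIO(text), sep=sep, header=header, dtype=str, skip_blank_lines=True)


def _to_float_column(col: pd.Series, name: str) -> np.ndarray:
    out = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(out))[0]
    if bad.size:
        raise MalformedInputError(
            f"non-numeric value in column {name!r} at data row {int(bad[0])}: "
            f"{col.iloc[int(bad[0])]!r}"
        )
    return out


def load_recording(
    path,
    *,
    subject_id: str = "",
    sample_rate: float | None = None,
    time_column: str | int | None = None,
    force_column: str | int | None = None,
    session_label: str = "",
) -> ForceRecording:
    """Load a force recording from a delimited text file.

    The file may contain either a time column (seconds, constant spacing
    within a 1% jitter tolerance) plus a force column, or a single force
    column with ``sample_rate`` supplied explicitly.  Columns may be named
    via header or addressed by position.

    Raises
    ------
    MalformedInputError
        If the time grid is nonuniform beyond tolerance, a cell is
        non-numeric, or neither a time column nor a sample rate is available.
    """
    df = _read_table(path)
    cols = list(df.columns)

    def _resolve(sel, default_idx):
        if sel is None:
            return cols[default_idx] if default_idx < len(cols) else None
        if isinstance(sel, int):
            return cols[sel]
        if sel not in cols:
            raise MalformedInputError(f"column {sel!r} not found (have {cols})")
        return sel

    if len(cols) >= 2:
        tcol = _resolve(time_column, 0)
        fcol = _resolve(force_column, 1)
        t = _to_float_column(df[tcol], str(tcol))
        f = _to_float_column(df[fcol], str(fcol))
        dt = np.diff(t)
        if dt.size == 0:
            raise MalformedInputError("recording must contain at least two samples")
        mean_dt = float(np.mean(dt))
        if mean_dt <= 0:
            raise MalformedInputError("time column is not strictly increasing")
        if np.max(np.abs(dt - mean_dt)) > TIME_JITTER_TOL * mean_dt:
            raise MalformedInputError(
                "nonuniform time grid: spacing deviates more than "
                f"{TIME_JITTER_TOL:.0%} from the mean interval {mean_dt:.6g} s"
            )
        inferred = 1.0 / mean_dt
        if sample_rate is not None and abs(sample_rate - inferred) > 0.01 * inferred:
            raise MalformedInputError(
                f"declared sample rate {sample_rate} Hz disagrees with the "
                f"time column ({inferred:.6g} Hz)"
            )
        rate = sample_rate if sample_rate is not None else inferred
    else:
        if sample_rate is None:
            raise MalformedInputError(
                "single-column recording requires an explicit sample_rate"
            )
        fcol = _resolve(force_column, 0)
        f = _to_float_column(df[fcol], str(fcol))
        rate = float(sample_rate)

    sid = subject_id or (Path(path).stem if isinstance(path, (str, Path)) else "")
    return ForceRecording(
        subject_id=sid, sample_rate=float(rate), force=f, session_label=session_label
    )


def save_recording(rec: ForceRecording, path) -> None:
    """Write a recording as two-column CSV (time in s, force)."""
    df = pd.DataFrame({"time_s": rec.times(), "force": rec.force})
    df.to_csv(path, index=False, float_format="%.10g")


def load_subject_table(path) -> list[SubjectRecord]:
    """Load subject metadata: one CSV row per subject.

    Required columns: ``subject_id``, ``group``.  A ``mvc_n`` column supplies
    the MVC in newtons; any remaining numeric columns are carried as
    covariates.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise MalformedInputError(f"subject table missing columns: {sorted(missing)}")
    records = []
    covariate_cols = [c for c in df.columns if c not in ("subject_id", "group", "mvc_n")]
    for _, row in df.iterrows():
        cov = {}
        for c in covariate_cols:
            v = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.notna(v):
                cov[c] = float(v)
        mvc = None
        if "mvc_n" in df.columns and pd.notna(row["mvc_n"]):
            mvc = float(row["mvc_n"])
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                mvc_force=mvc,
                covariates=cov,
            )
        )
    return records


def best_mvc(trial_forces) -> float:
    """Greatest of the per-trial MVC peak forces (newtons).

    The strongest of the (typically three) maximal contraction trials is the
    normalization denominator for the whole session.
    """
    trials = np.asarray(list(trial_forces), dtype=float)
    if trials.size == 0:
        raise ValueError("best_mvc requires at least one trial value")
    if not np.all(np.isfinite(trials)) or np.any(trials <= 0):
        raise ValueError("MVC trial values must be finite and positive")
    return float(trials.max())


def normalize_to_mvc(rec: ForceRecording, mvc: float) -> ForceRecording:
    """Express force as percent of MVC: each sample maps to ``100 * F / mvc``."""
    if mvc <= 0 or not np.isfinite(mvc):
        raise ValueError(f"MVC must be positive and finite, got {mvc}")
    if rec.normalized:
        raise MalformedInputError("recording is already normalized")
    return replace(rec, force=100.0 * rec.force / mvc, mvc_force=float(mvc), normalized=True)
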