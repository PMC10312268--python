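"""Reading, validation, and preparation of ROI time series and task events.

This module handles the plumbing around already-extracted region-of-interest
(ROI) signals: parsing delimited text tables, building hemodynamic task
regressors from event tables, per-column standardization, and the
participant-level quality-control (QC) exclusion arithmetic applied before
any network estimation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "TaskEvents",
    "QCRecord",
    "read_timeseries",
    "write_timeseries",
    "read_events",
    "build_task_regressors",
    "standardize",
    "qc_exclude",
    "read_qc_table",
]

#: minimum usable length, as a multiple of the number of columns
MIN_LENGTH_FACTOR = 3


class TimeSeriesError(ValueError):
    """Raised for malformed or degenerate time-series input."""


@dataclass
class ROITimeSeries:
    """One subject's endogenous node series plus exogenous task regressors.

    Parameters
    ----------
    subject_id : str
        Subject label.
    values : ndarray, shape (T, p)
        Endogenous ROI signals, arbitrary units.
    node_names : list of str
        Labels of the p endogenous nodes.
    exogenous : ndarray, shape (T, q)
        Exogenous (task) regressor columns; q may be 0.
    exogenous_names : list of str
        Labels of the exogenous columns.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    """

    subject_id: str
    values: np.ndarray
    node_names: list[str]
    exogenous: np.ndarray = None
    exogenous_names: list[str] = field(default_factory=list)
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TimeSeriesError("values must be a 2-D (T, p) array")
        T, p = self.values.shape
        if len(self.node_names) != p:
            raise TimeSeriesError(
                f"{len(self.node_names)} node names for {p} columns"
            )
        if self.exogenous is None:
            self.exogenous = np.zeros((T, 0))
        self.exogenous = np.asarray(self.exogenous, dtype=float)
        if self.exogenous.shape[0] != T:
            raise TimeSeriesError("exogenous rows must match values rows")
        if len(self.exogenous_names) != self.exogenous.shape[1]:
            raise TimeSeriesError("exogenous_names length mismatch")
        names = self.node_names + self.exogenous_names
        if len(set(names)) != len(names):
            raise TimeSeriesError("node and exogenous names must be unique")
        if np.isnan(self.values).any() or np.isnan(self.exogenous).any():
            raise TimeSeriesError("missing values in time series")
        min_T = MIN_LENGTH_FACTOR * (p + self.exogenous.shape[1])
        if T < min_T:
            raise TimeSeriesError(
                f"series of length {T} shorter than minimum {min_T} "
                f"(3x the number of columns)"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_exogenous(self) -> int:
        return self.exogenous.shape[1]


@dataclass
class TaskEvents:
    """Task event table: onsets/durations in seconds with a trial type."""

    table: pd.DataFrame  # columns: onset, duration, trial_type

    def __post_init__(self):
        required = {"onset", "duration", "trial_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise TimeSeriesError(f"event table missing columns: {sorted(missing)}")
        t = self.table.sort_values("onset", kind="stable").reset_index(drop=True)
        if len(t) and (t["onset"] < 0).any():
            raise TimeSeriesError("negative event onset")
        if len(t) and (t["duration"] < 0).any():
            raise TimeSeriesError("negative event duration")
        self.table = t

    @property
    def trial_types(self) -> list[str]:
        return sorted(self.table["trial_type"].unique())

    def __len__(self):
        return len(self.table)


@dataclass
class QCRecord:
    """Per-subject quality-control summary.

    mean_fd_mm : mean framewise displacement (mm); tsnr : temporal
    signal-to-noise ratio; frame_fd_mm : optional per-frame FD vector;
    compliance_fraction : fraction of task trials with valid responses.
    """

    subject_id: str
    mean_fd_mm: float
    tsnr: float
    frame_fd_mm: np.ndarray | None = None
    compliance_fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.compliance_fraction <= 1.0):
            raise TimeSeriesError(
                f"compliance_fraction {self.compliance_fraction} outside [0, 1]"
            )
        if self.frame_fd_mm is not None:
            self.frame_fd_mm = np.asarray(self.frame_fd_mm, dtype=float)


def _sniff_delimiter(header_line: str) -> str | None:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return None  # whitespace


def read_timeseries(path, tr_seconds: float = 2.0,
                    exogenous_names: list[str] | None = None,
                    subject_id: str | None = None) -> ROITimeSeries:
    """Read a headered delimited table of one subject's series.

    Columns named in ``exogenous_names`` are treated as exogenous task
    regressors; all others are endogenous nodes. The delimiter is detected
    among comma, tab, and whitespace.
    """
    with open(path) as fh:
        first = fh.readline()
        body = first + fh.read()
    delim = _sniff_delimiter(first)
    header = (first.strip().split(delim) if delim
              else first.strip().split())
    seen, dups = set(), []
    for name in header:
        if name in seen:
            dups.append(name)
        seen.add(name)
    if dups:
        raise TimeSeriesError(f"{path}: duplicate header names {dups}")
    kwargs = {"sep": delim} if delim else {"sep": r"\s+"}
    try:
        df = pd.read_csv(io.StringIO(body), **kwargs)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TimeSeriesError(f"{path}: cannot parse: {exc}") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nan_rows = np.nonzero(bad.isna().to_numpy())[0]
        if nan_rows.size:
            raise TimeSeriesError(
                f"{path}: non-numeric or missing cell at row {nan_rows[0] + 1}, "
                f"column '{col}'"
            )
    exo = list(exogenous_names or [])
    missing = [c for c in exo if c not in df.columns]
    if missing:
        raise TimeSeriesError(f"{path}: exogenous columns not found: {missing}")
    endo = [c for c in df.columns if c not in exo]
    sid = subject_id if subject_id is not None else str(path)
    return ROITimeSeries(
        subject_id=sid,
        values=df[endo].to_numpy(float),
        node_names=endo,
        exogenous=df[exo].to_numpy(float) if exo else None,
        exogenous_names=exo,
        tr_seconds=tr_seconds,
    )


def write_timeseries(series: ROITimeSeries, path, sep: str = ",") -> None:
    """Write a series (endogenous + exogenous columns) as headered text."""
    data = np.hstack([series.values, series.exogenous])
    df = pd.DataFrame(data, columns=series.node_names + series.exogenous_names)
    df.to_csv(path, sep=sep, index=False)


def read_events(path) -> TaskEvents:
    """Read a BIDS-style events table (tab-separated: onset, duration, trial_type)."""
    df = pd.read_csv(path, sep="\t")
    return TaskEvents(df)


def _double_gamma_hrf(t: np.ndarray, peak_delay: float = 6.0,
                      undershoot_delay: float = 16.0,
                      peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                      undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t``."""
    from scipy import stats

    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    return h


def build_task_regressors(events: TaskEvents, T: int, tr_seconds: float,
                          hrf_params: dict | None = None,
                          oversample: int = 20) -> tuple[np.ndarray, list[str]]:
    """Build one HRF-convolved regressor column per trial type.

    Each trial type's events form a boxcar on a fine time grid
    (``tr_seconds / oversample`` resolution), which is convolved with the
    canonical double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1,
    undershoot ratio 1/6, kernel length 32 s), sampled at frame-onset times
    t = i * TR, truncated to ``T`` frames, and scaled to unit peak.

    Returns
    -------
    (T, q) regressor matrix and the ordered list of trial-type names.
    """
    params = dict(peak_delay=6.0, undershoot_delay=16.0, peak_disp=1.0,
                  undershoot_disp=1.0, undershoot_ratio=1.0 / 6.0,
                  length=32.0)
    params.update(hrf_params or {})
    length = params.pop("length")
    scan_end = T * tr_seconds
    tab = events.table
    if len(tab) and (tab["onset"] >= scan_end).any():
        bad = tab.loc[tab["onset"] >= scan_end].iloc[0]
        raise TimeSeriesError(
            f"event at onset {bad['onset']:.1f}s lies past scan end "
            f"({scan_end:.1f}s)"
        )
    dt = tr_seconds / oversample
    grid = np.arange(0.0, scan_end + length, dt)
    hrf = _double_gamma_hrf(np.arange(0.0, length, dt), **params)
    types = events.trial_types
    cols = np.zeros((T, len(types)))
    frame_times = np.arange(T) * tr_seconds
    frame_idx = np.round(frame_times / dt).astype(int)
    for ci, ttype in enumerate(types):
        box = np.zeros_like(grid)
        for _, ev in tab[tab["trial_type"] == ttype].iterrows():
            i0 = int(np.round(ev["onset"] / dt))
            i1 = int(np.round((ev["onset"] + ev["duration"]) / dt))
            box[i0:max(i1, i0 + 1)] = 1.0  # zero-duration events act as impulses
        conv = np.convolve(box, hrf)[: len(grid)]
        col = conv[frame_idx]
        peak = np.abs(col).max()
        if peak > 0:
            col = col / peak
        cols[:, ci] = col
    return cols, list(types)


def standardize(series: ROITimeSeries,
                include_exogenous: bool = True) -> ROITimeSeries:
    """Return a copy with each column z-scored (mean 0, SD 1).

    Exogenous columns are standardized too by default, which puts their
    path coefficients on the same scale as endogenous ones.
    """
    def _z(mat: np.ndarray, names: list[str]) -> np.ndarray:
        if mat.shape[1] == 0:
            return mat
        sd = mat.std(axis=0, ddof=0)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise TimeSeriesError(
                f"zero-variance column '{names[zero[0]]}' cannot be standardized"
            )
        return (mat - mat.mean(axis=0)) / sd

    new_vals = _z(series.values, series.node_names)
    new_exo = (_z(series.exogenous, series.exogenous_names)
               if include_exogenous else series.exogenous.copy())
    return replace(series, values=new_vals, exogenous=new_exo)


def _tukey_fences(x: np.ndarray, factor: float) -> tuple[float, float]:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return q1 - factor * iqr, q3 + factor * iqr


def qc_exclude(records: list[QCRecord], iqr_factor: float = 1.5,
               frame_fd_threshold_mm: float = 2.0,
               frame_fraction: float = 0.25,
               compliance_min: float = 0.75):
    """Apply the staged participant-level QC exclusion rules.

    Stages, applied sequentially with quartiles recomputed over the
    currently retained set:

    1. behavioral compliance below ``compliance_min``;
    2. tSNR below Q1 - ``iqr_factor`` * IQR (low-quality signal);
    3. mean FD above Q3 + ``iqr_factor`` * IQR (excessive motion);
    4. more than ``frame_fraction`` of frames with FD >=
       ``frame_fd_threshold_mm``.

    Returns
    -------
    (kept_ids, excluded) where ``excluded`` is a list of
    (subject_id, reason) tuples in exclusion order.
    """
    if len(records) < 4:
        raise TimeSeriesError("at least 4 records required for IQR rules")
    excluded: list[tuple[str, str]] = []
    kept = list(records)

    # stage 1: behavioral compliance
    still = []
    for r in kept:
        if r.compliance_fraction < compliance_min:
            excluded.append((r.subject_id, "compliance"))
        else:
            still.append(r)
    kept = still

    # stage 2: low tSNR outliers (Tukey fence, harmful side only)
    if kept:
        low, _ = _tukey_fences(np.array([r.tsnr for r in kept]), iqr_factor)
        still = []
        for r in kept:
            if r.tsnr < low:
                excluded.append((r.subject_id, "tsnr"))
            else:
                still.append(r)
        kept = still

    # stage 3: high mean-FD outliers
    if kept:
        _, high = _tukey_fences(np.array([r.mean_fd_mm for r in kept]),
                                iqr_factor)
        still = []
        for r in kept:
            if r.mean_fd_mm > high:
                excluded.append((r.subject_id, "mean-FD"))
            else:
                still.append(r)
        kept = still

    # stage 4: fraction of high-motion frames
    still = []
    for r in kept:
        if r.frame_fd_mm is not None and r.frame_fd_mm.size:
            frac = float(np.mean(r.frame_fd_mm >= frame_fd_threshold_mm))
            if frac > frame_fraction:
                excluded.append((r.subject_id, "frame-FD fraction"))
                continue
        still.append(r)
    kept = still

    return [r.subject_id for r in kept], excluded


def read_qc_table(path, frame_fd: dict[str, np.ndarray] | None = None
                  ) -> list[QCRecord]:
    """Read a QC CSV with columns subject_id, mean_fd_mm, tsnr and optional
    compliance_fraction; per-frame FD vectors may be supplied separately."""
    df = pd.read_csv(path)
    required = {"subject_id", "mean_fd_mm", "tsnr"}
    missing = required - set(df.columns)
    if missing:
        raise TimeSeriesError(f"QC table missing columns: {sorted(missing)}")
    recs = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        recs.append(QCRecord(
            subject_id=sid,
            mean_fd_mm=float(row["mean_fd_mm"]),
            tsnr=float(row["tsnr"]),
            compliance_fraction=float(row.get("compliance_fraction", 1.0)),
            frame_fd_mm=(frame_fd or {}).get(sid),
        ))
    return recs
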