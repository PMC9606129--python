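"""Sliding-window Φ analysis of a full recording.

A 900 s recording sampled at 250 Hz is cut into one analysis window per
250-frame step (900 steps for a full recording).  Each window yields a
whole-system MIP result and a complex report; the per-step series carry
phase labels (pre/stim/post thirds of the timeline), can be linearly
detrended for the phase statistics, and a trailing moving average is
available for display.  The τ-scan picks the analysis lag that maximises
mean whole-system Φ_MIP across recordings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .complexes import ComplexReport, summarize_complexes
from .gaussian import PhiResult, estimate_lagged_model, mip_search

__all__ = [
    "CHANNELS",
    "PHASES",
    "Recording",
    "WindowConfig",
    "SubjectSeries",
    "sliding_windows",
    "run_subject",
    "detrend_series",
    "moving_average",
    "tau_scan",
]

log = logging.getLogger(__name__)

#: canonical channel order: body (respiration, heartbeat, skin conductance)
#: then midline EEG front to back.
CHANNELS = ("RES", "ECG", "EDA", "Fz", "Cz", "Pz", "Oz")

#: phase name -> [start, stop) in steps for a full 900-step recording.
PHASES = {"pre": (0, 300), "stim": (300, 600), "post": (600, 900)}

EXPECTED_FRAMES = 225_000
CONDITIONS = ("SYNC", "ASYNC")


@dataclass
class Recording:
    """One subject × condition block of multichannel physiological data."""

    subject_id: str
    condition: str
    data: np.ndarray  # frames x channels
    rate: float = 250.0
    labels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.labels):
            raise ValueError(
                f"data must be frames x {len(self.labels)} channels, got {self.data.shape}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if tuple(self.labels) != CHANNELS:
            raise ValueError(f"channel labels must be {CHANNELS} in order, got {self.labels}")
        if self.data.shape[0] != EXPECTED_FRAMES:
            warnings.warn(
                f"recording has {self.data.shape[0]} frames, expected {EXPECTED_FRAMES} "
                "(900 s at 250 Hz)",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class WindowConfig:
    """Windowing and lag settings for the per-step Φ computation.

    ``stride`` computes every stride-th step only (cost control for cohort
    runs); statistics then use the computed steps.
    """

    window_len: int = 250
    shift: int = 250
    tau: int = 50
    ridge: Optional[float] = None
    stride: int = 1

    def __post_init__(self):
        if self.window_len < self.tau + 2:
            raise ValueError(
                f"window_len={self.window_len} too short for tau={self.tau}"
            )
        if self.shift < 1 or self.stride < 1:
            raise ValueError("shift and stride must be >= 1")


def phase_of_step(step: int, n_steps: int = 900) -> str:
    """Phase label for a step index: first third pre, middle stim, last post."""
    third = n_steps // 3
    if step < third:
        return "pre"
    if step < 2 * third:
        return "stim"
    return "post"


def sliding_windows(
    recording: Recording, config: WindowConfig
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (step, window) pairs; step t's window ends at frame (t+1)·shift.

    The window covers frames [(t+1)·shift − window_len, (t+1)·shift); frames
    before the recording start are zero-filled, which touches at most the
    first few steps when window_len exceeds shift.
    """
    data = recording.data
    n_steps = data.shape[0] // config.shift
    n_ch = data.shape[1]
    for step in range(n_steps):
        end = (step + 1) * config.shift
        start = end - config.window_len
        if start >= 0:
            yield step, data[start:end]
        else:
            pad = np.zeros((-start, n_ch))
            yield step, np.vstack([pad, data[:end]])


@dataclass
class SubjectSeries:
    """Per-step Φ and complex results for one recording.

    ``table`` has one row per computed step with columns: step, phase,
    phi_mip, mip_cut, mutual_info, sum_main_phi, n_complexes, n_main,
    max_main_subset, max_main_phi, missing.  Detrended copies of phi_mip and
    sum_main_phi are added by :meth:`detrended`.
    """

    subject_id: str
    condition: str
    config: WindowConfig
    table: pd.DataFrame
    phi_results: list[Optional[PhiResult]] = field(default_factory=list, repr=False)
    complex_reports: list[Optional[ComplexReport]] = field(default_factory=list, repr=False)

    def detrended(self) -> pd.DataFrame:
        """Table with ``phi_mip_dt`` and ``sum_main_phi_dt`` columns added."""
        out = self.table.copy()
        for col in ("phi_mip", "sum_main_phi"):
            vals = out[col].to_numpy()
            if np.isfinite(vals).sum() == 0:  # measure not computed
                out[col + "_dt"] = np.nan
                continue
            out[col + "_dt"] = detrend_series(vals, out["missing"].to_numpy())
        return out


def run_subject(
    recording: Recording,
    config: WindowConfig = WindowConfig(),
    compute_complexes: bool = True,
) -> SubjectSeries:
    """Compute the whole-system MIP result (and optionally the complex
    report) for every selected window of a recording.

    Windows containing a constant channel are flagged missing and excluded
    from downstream statistics rather than imputed.
    """
    rows = []
    phi_results: list[Optional[PhiResult]] = []
    complex_reports: list[Optional[ComplexReport]] = []
    n_steps = recording.n_frames // config.shift
    labels = recording.labels
    for step, window in sliding_windows(recording, config):
        if config.stride > 1 and step % config.stride != 0:
            continue
        phase = phase_of_step(step, n_steps)
        row = {
            "step": step,
            "phase": phase,
            "missing": False,
            "phi_mip": np.nan,
            "mip_cut": "",
            "mutual_info": np.nan,
            "sum_main_phi": np.nan,
            "n_complexes": 0,
            "n_main": 0,
            "max_main_subset": "",
            "max_main_phi": np.nan,
        }
        # all-zero padding or flat-lined sensors make the window degenerate
        span = window.max(axis=0) - window.min(axis=0)
        if np.any(span == 0.0):
            flat = [labels[i] for i in np.where(span == 0.0)[0]]
            log.warning(
                "%s/%s step %d: constant channel(s) %s; window excluded",
                recording.subject_id, recording.condition, step, ",".join(flat),
            )
            row["missing"] = True
            rows.append(row)
            phi_results.append(None)
            complex_reports.append(None)
            continue
        model = estimate_lagged_model(
            window, tau=config.tau, ridge=config.ridge, labels=labels
        )
        phi = mip_search(model)
        row["phi_mip"] = phi.phi_mip
        row["mip_cut"] = phi.mip.key(labels)
        row["mutual_info"] = phi.mutual_info
        phi_results.append(phi)
        if compute_complexes:
            rep = summarize_complexes(model)
            row["sum_main_phi"] = rep.sum_main_phi
            row["n_complexes"] = rep.n_complexes
            row["n_main"] = len(rep.main_complexes)
            if rep.max_main is not None:
                row["max_main_subset"] = rep.subset_key(rep.max_main[0])
                row["max_main_phi"] = rep.max_main[1]
            complex_reports.append(rep)
        else:
            complex_reports.append(None)
        rows.append(row)
    table = pd.DataFrame(rows)
    return SubjectSeries(
        subject_id=recording.subject_id,
        condition=recording.condition,
        config=config,
        table=table,
        phi_results=phi_results,
        complex_reports=complex_reports,
    )


def detrend_series(values: np.ndarray, missing: Optional[np.ndarray] = None) -> np.ndarray:
    """Subtract the least-squares line fitted to the whole series.

    Missing entries are ignored in the fit and returned as NaN.  Detrended Φ
    can legitimately go negative.
    """
    values = np.asarray(values, dtype=float)
    if missing is None:
        ok = np.isfinite(values)
    else:
        ok = ~np.asarray(missing, dtype=bool) & np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("detrending needs at least 2 non-missing points")
    t = np.arange(values.size, dtype=float)
    slope, intercept = np.polyfit(t[ok], values[ok], 1)
    out = values - (slope * t + intercept)
    out[~ok] = np.nan
    return out


def moving_average(values: np.ndarray, length: int = 150) -> np.ndarray:
    """Trailing moving average for display; never used in statistics.

    Entry t averages the values at steps max(0, t−length+1)…t.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    values = np.asarray(values, dtype=float)
    kernel = np.ones(length)
    num = np.convolve(values, kernel, mode="full")[: values.size]
    den = np.convolve(np.ones_like(values), kernel, mode="full")[: values.size]
    return num / den


def tau_scan(
    recordings: Sequence[Recording],
    taus: Sequence[int] = range(0, 251),
    config: WindowConfig = WindowConfig(),
    window_stride: int = 10,
    scan_window_len: int = 1000,
) -> tuple[int, pd.DataFrame]:
    """Pick the analysis lag: the τ maximising mean whole-system Φ_MIP.

    Every ``window_stride``-th window of every recording contributes; ties
    go to the smallest τ.  The scan uses its own, longer window
    (``scan_window_len``) so that the number of lagged pairs — and with it
    the small-sample bias of the Φ estimate — stays comparable across the
    whole τ range; with the per-step analysis window the bias alone would
    grow with τ and distort the profile.  Returns (selected τ, profile table
    with columns tau and mean_phi).
    """
    taus = [int(t) for t in taus]
    if not taus:
        raise ValueError("empty tau range")
    if not recordings:
        raise ValueError("need at least one recording")
    means = []
    for tau in taus:
        cfg = replace(config, tau=tau, stride=window_stride,
                      window_len=max(scan_window_len, tau + 2))
        vals = []
        for rec in recordings:
            series = run_subject(rec, cfg, compute_complexes=False)
            vals.append(series.table.loc[~series.table.missing, "phi_mip"])
        means.append(float(pd.concat(vals).mean()))
        log.info("tau scan: tau=%d mean phi=%.6g", tau, means[-1])
    profile = pd.DataFrame({"tau": taus, "mean_phi": means})
    best = int(profile.loc[profile.mean_phi.idxmax(), "tau"])
    # idxmax returns the first maximum, which is the smallest tau in the scan
    return best, profile
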