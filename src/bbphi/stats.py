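"""Phase statistics, cut/complex frequency differences, and the subject score.

Implements the group-level analyses: Welch t-tests contrasting the detrended
Φ series between phases, per-subject frequency shifts of MIP cuts and of the
strongest main complex between the pre and stimulus phases, the per-subject
condition-difference score s(Φ_MIP), the questionnaire-based illusion index,
and Pearson correlation between the two.

All p-values are raw (no multiple-testing correction): the downstream
reporting mirrors starred raw p-values, so any correction is left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import SubjectSeries

__all__ = [
    "PhaseContrast",
    "FrequencyDiff",
    "SubjectScore",
    "phase_contrast",
    "mip_cut_frequency_diff",
    "main_complex_frequency_diff",
    "s_statistic",
    "peak_end_summary",
    "rhi_index",
    "correlate",
    "RHI_ITEMS",
    "EXTENDED_ITEMS",
]

#: questionnaire items averaged into the illusion index (referral of touch +
#: ownership) and the extended variant that adds the two control items whose
#: condition differences track ownership.
RHI_ITEMS = ("Q1", "Q2", "Q3")
EXTENDED_ITEMS = ("Q1", "Q2", "Q3", "Q7", "Q8")

PHASE_PAIRS = (("pre", "stim"), ("stim", "post"), ("pre", "post"))


@dataclass
class PhaseContrast:
    """Welch t-tests between phase-pooled window values for one measure."""

    measure: str
    phase_means: dict[str, float]
    phase_counts: dict[str, int]
    tests: pd.DataFrame  # columns: phase_a, phase_b, t, df, p


@dataclass(frozen=True)
class FrequencyDiff:
    """Mean per-subject frequency difference Fr(key|stim) − Fr(key|pre)."""

    key: str
    diff: float
    condition: str


@dataclass
class SubjectScore:
    """Per-subject quantities entering the correlation analysis."""

    subject_id: str
    s_phi: float
    rhi_sync: float
    rhi_async: float
    extended_diff: float = np.nan
    ratings: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def rhi_diff(self) -> float:
        return self.rhi_sync - self.rhi_async


def _pooled_phase_values(
    series_by_subject: Mapping[str, SubjectSeries], measure: str
) -> dict[str, np.ndarray]:
    col = measure + "_dt"
    pooled: dict[str, list[np.ndarray]] = {"pre": [], "stim": [], "post": []}
    for series in series_by_subject.values():
        t = series.detrended()
        t = t[~t.missing]
        for phase in pooled:
            pooled[phase].append(t.loc[t.phase == phase, col].to_numpy())
    return {ph: np.concatenate(v) if v else np.array([]) for ph, v in pooled.items()}


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, Welch–Satterthwaite df, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each phase needs at least 2 values for a Welch test")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def phase_contrast(
    series_by_subject: Mapping[str, SubjectSeries],
    measure: str = "phi_mip",
    per_subject: bool = False,
) -> PhaseContrast:
    """Welch-test detrended window values between phases.

    ``measure`` is a per-step column (``phi_mip`` or ``sum_main_phi``); its
    detrended version is used.  By default windows are pooled across
    subjects (large degrees of freedom); with ``per_subject`` each subject
    contributes one mean per phase instead.  p-values are raw.
    """
    if per_subject:
        col = measure + "_dt"
        pooled = {"pre": [], "stim": [], "post": []}
        for series in series_by_subject.values():
            t = series.detrended()
            t = t[~t.missing]
            for phase in pooled:
                pooled[phase].append(t.loc[t.phase == phase, col].mean())
        pooled = {ph: np.asarray(v, float) for ph, v in pooled.items()}
    else:
        pooled = _pooled_phase_values(series_by_subject, measure)
    rows = []
    for pa, pb in PHASE_PAIRS:
        t, df, p = welch_test(pooled[pa], pooled[pb])
        rows.append({"phase_a": pa, "phase_b": pb, "t": t, "df": df, "p": p})
    return PhaseContrast(
        measure=measure,
        phase_means={ph: float(np.mean(v)) for ph, v in pooled.items()},
        phase_counts={ph: int(v.size) for ph, v in pooled.items()},
        tests=pd.DataFrame(rows),
    )


def _frequency_diff(
    series_by_subject: Mapping[str, SubjectSeries],
    condition: str,
    column: str,
) -> list[FrequencyDiff]:
    per_subject: list[pd.Series] = []
    for series in series_by_subject.values():
        if series.condition != condition:
            continue
        t = series.table
        t = t[~t.missing & (t[column] != "")]
        fr = {}
        for phase in ("pre", "stim"):
            sub = t.loc[t.phase == phase, column]
            fr[phase] = sub.value_counts(normalize=True) if len(sub) else pd.Series(dtype=float)
        per_subject.append(fr["stim"].sub(fr["pre"], fill_value=0.0))
    if not per_subject:
        raise ValueError(f"no series for condition {condition!r}")
    mean_diff = pd.concat(per_subject, axis=1).fillna(0.0).mean(axis=1)
    mean_diff = mean_diff.sort_values(ascending=False)
    return [FrequencyDiff(key=str(k), diff=float(v), condition=condition)
            for k, v in mean_diff.items()]


def mip_cut_frequency_diff(
    series_by_subject: Mapping[str, SubjectSeries], condition: str
) -> list[FrequencyDiff]:
    """Stim-minus-pre frequency shift of each whole-system MIP cut.

    Frequencies are computed per subject (each subject's windows normalise
    to 1 within a phase), then averaged across subjects; the result is
    sorted by descending shift and sums to zero over all cuts.
    """
    return _frequency_diff(series_by_subject, condition, "mip_cut")


def main_complex_frequency_diff(
    series_by_subject: Mapping[str, SubjectSeries], condition: str
) -> list[FrequencyDiff]:
    """Stim-minus-pre frequency shift of the strongest-main-complex subset."""
    return _frequency_diff(series_by_subject, condition, "max_main_subset")


def _baseline_subtracted_stim(series: SubjectSeries, measure: str) -> pd.Series:
    t = series.table
    ok = ~t.missing
    pre = t.loc[ok & (t.phase == "pre"), measure]
    if pre.empty:
        raise ValueError("no pre-phase values to form the baseline")
    baseline = pre.mean()
    stim = t.loc[ok & (t.phase == "stim")].set_index("step")[measure]
    return stim - baseline


def s_statistic(
    sync: SubjectSeries, async_: SubjectSeries, measure: str = "sum_main_phi"
) -> float:
    """Per-subject condition-difference score s(Φ_MIP).

    Each condition's ΣΦ-over-main-complexes series is baselined by its own
    mean pre-stimulus value; the score is the sum over stimulus-phase steps
    of the SYNC-minus-ASYNC baseline-subtracted difference.  Adding a
    constant to all windows of one condition leaves it unchanged, and
    swapping the conditions flips its sign.
    """
    if sync.condition != "SYNC" or async_.condition != "ASYNC":
        raise ValueError("pass the SYNC series first and the ASYNC series second")
    s = _baseline_subtracted_stim(sync, measure)
    a = _baseline_subtracted_stim(async_, measure)
    steps = s.index.intersection(a.index)
    if steps.empty:
        raise ValueError("no overlapping stimulus-phase steps between conditions")
    return float((s.loc[steps] - a.loc[steps]).sum())


def peak_end_summary(
    sync: SubjectSeries, async_: SubjectSeries, measure: str = "sum_main_phi"
) -> float:
    """Peak–end variant of the subject score.

    Per condition: mean of the maximum and the final baseline-subtracted
    stimulus-phase value; returns the SYNC-minus-ASYNC difference.
    """
    out = {}
    for series in (sync, async_):
        v = _baseline_subtracted_stim(series, measure).dropna()
        if v.empty:
            raise ValueError("no stimulus-phase values")
        out[series.condition] = 0.5 * (v.max() + v.iloc[-1])
    return float(out["SYNC"] - out["ASYNC"])


def rhi_index(ratings: pd.DataFrame, subject_id: Optional[str] = None) -> pd.DataFrame:
    """Illusion index per subject × condition plus condition differences.

    ``ratings`` needs columns subject_id, condition, Q1…Q9 (0–100 scale).
    Returns one row per subject with rhi_sync, rhi_async, rhi_diff, the
    per-item differences dQ1…dQ9 and the extended mean over dQ1, dQ2, dQ3,
    dQ7, dQ8.
    """
    req = {"subject_id", "condition", *(f"Q{i}" for i in range(1, 10))}
    missing = req - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table is missing columns: {sorted(missing)}")
    qcols = [f"Q{i}" for i in range(1, 10)]
    vals = ratings[qcols].to_numpy(float)
    if np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 100:
        raise ValueError("ratings must be finite and within the 0-100 scale")
    if subject_id is not None:
        ratings = ratings[ratings.subject_id == subject_id]
    rows = []
    for sid, grp in ratings.groupby("subject_id", sort=True):
        conds = {c: g.iloc[0] for c, g in grp.groupby("condition")}
        if "SYNC" not in conds or "ASYNC" not in conds:
            raise ValueError(f"subject {sid}: need both SYNC and ASYNC ratings")
        row = {"subject_id": sid}
        for cond in ("SYNC", "ASYNC"):
            row[f"rhi_{cond.lower()}"] = float(
                np.mean([conds[cond][q] for q in RHI_ITEMS])
            )
        row["rhi_diff"] = row["rhi_sync"] - row["rhi_async"]
        for q in qcols:
            row[f"d{q}"] = float(conds["SYNC"][q] - conds["ASYNC"][q])
        row["extended_diff"] = float(np.mean([row[f"d{q}"] for q in EXTENDED_ITEMS]))
        rows.append(row)
    return pd.DataFrame(rows)


def correlate(scores: Sequence[SubjectScore] | pd.DataFrame,
              y: str = "rhi_diff") -> tuple[float, int, float]:
    """Pearson correlation between s(Φ_MIP) and a rating difference.

    Accepts a list of :class:`SubjectScore` or a DataFrame with columns
    ``s_phi`` and ``y``; returns (r, n, two-sided p).
    """
    if isinstance(scores, pd.DataFrame):
        df = scores
        xs = df["s_phi"].to_numpy(float)
        ys = df[y].to_numpy(float)
    else:
        xs = np.array([s.s_phi for s in scores], float)
        ys = np.array([getattr(s, y) for s in scores], float)
    ok = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[ok], ys[ok]
    if xs.size < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    r, p = sps.pearsonr(xs, ys)
    return float(r), int(xs.size), float(p)
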