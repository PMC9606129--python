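"""Reading recordings and ratings; writing tidy result tables with provenance.

Recordings travel as delimited text (one header row of channel labels, one
row per frame) plus a JSON sidecar carrying subject, condition and sampling
rate; a ``sub-<id>_<COND>.csv`` filename convention is the fallback when no
sidecar exists.  Every output directory receives a ``run_meta.json`` with
the configuration, seed and package version so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .pipeline import CHANNELS, CONDITIONS, Recording, SubjectSeries, WindowConfig

__all__ = [
    "read_recording",
    "write_recording",
    "read_ratings",
    "write_results",
    "write_run_meta",
]

_NAME_RE = re.compile(r"sub-(?P<subject>[A-Za-z0-9]+)_(?P<condition>SYNC|ASYNC)")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(path, rate: Optional[float] = None) -> Recording:
    """Read a delimited-text recording (+ optional JSON sidecar metadata).

    The header row must name the seven canonical channels; a missing or
    extra column, ragged rows and non-numeric cells are reported by name.
    ``rate`` overrides the sidecar/default sampling rate.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text ({exc})") from exc
    got = tuple(df.columns)
    missing = [c for c in CHANNELS if c not in got]
    if missing:
        raise ValueError(
            f"{path}: missing channel column(s) {', '.join(missing)}; "
            f"expected exactly {CHANNELS}"
        )
    extra = [c for c in got if c not in CHANNELS]
    if extra:
        raise ValueError(f"{path}: unknown channel column(s) {', '.join(extra)}")
    data = df[list(CHANNELS)]
    bad = data.columns[data.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
    if len(bad):
        raise ValueError(f"{path}: non-numeric cells in column(s) {', '.join(bad)}")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    m = _NAME_RE.search(path.stem)
    subject = meta.get("subject_id") or (m.group("subject") if m else path.stem)
    condition = meta.get("condition") or (m.group("condition") if m else None)
    if condition not in CONDITIONS:
        raise ValueError(
            f"{path}: cannot determine condition (SYNC/ASYNC) from sidecar or filename"
        )
    eff_rate = rate or meta.get("rate", 250.0)
    return Recording(
        subject_id=str(subject),
        condition=condition,
        data=data.to_numpy(dtype=float),
        rate=float(eff_rate),
    )


def write_recording(recording: Recording, path) -> Path:
    """Write a recording as CSV plus its JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(recording.data, columns=list(recording.labels)).to_csv(
        path, index=False, float_format="%.6g"
    )
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "subject_id": recording.subject_id,
                "condition": recording.condition,
                "rate": recording.rate,
            },
            indent=1,
        )
    )
    return path


def read_ratings(path) -> pd.DataFrame:
    """Read the questionnaire table (subject_id, condition, Q1..Q9)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    need = ["subject_id", "condition"] + [f"Q{i}" for i in range(1, 10)]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ratings table missing column(s) {', '.join(missing)}")
    return df


def write_results(
    outdir,
    series: Optional[Mapping[str, SubjectSeries]] = None,
    tables: Optional[Mapping[str, pd.DataFrame]] = None,
) -> Path:
    """Write per-step series and any stats tables as tidy CSV files.

    Per-step tables land in ``<outdir>/series_<subject>_<condition>.csv``
    with the detrended columns included; each entry of ``tables`` is written
    as ``<outdir>/<name>.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if series:
        for s in series.values():
            t = s.detrended()
            t.insert(0, "condition", s.condition)
            t.insert(0, "subject_id", s.subject_id)
            t.to_csv(outdir / f"series_{s.subject_id}_{s.condition}.csv", index=False)
    for name, df in (tables or {}).items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    return outdir


def write_run_meta(outdir, config=None, seed: Optional[int] = None, **extra) -> Path:
    """Write run provenance (config, seed, package version) as JSON."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"bbphi_version": __version__, "seed": seed, **extra}
    if config is not None:
        if dataclasses.is_dataclass(config):
            cfg = dataclasses.asdict(config)
        else:
            cfg = dict(config)
        meta["config"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in cfg.items()
        }
    path = outdir / "run_meta.json"
    path.write_text(json.dumps(meta, indent=1, default=str))
    return path
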