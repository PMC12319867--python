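"""Physiological trace containers and file I/O.

Traces are uniformly sampled 1D signals (exhaled CO2, respiration-belt
effort, and everything derived from them).  Files follow the BIDS-physio
dialect: a (optionally gzipped) TSV of samples plus a JSON sidecar carrying
``SamplingFrequency``, ``StartTime`` and ``Columns``.  NIfTI volumes are
read and written here for all downstream modules.
"""
from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("volts", "mmHg", "arbitrary", "zscore")


class PhysioConfigError(Exception):
    """Missing or inconsistent acquisition metadata (e.g. sampling rate)."""


class PhysioParseError(Exception):
    """Malformed physio file content."""


class UnitError(Exception):
    """Operation applied to a trace in the wrong units."""


@dataclass
class Trace:
    """A uniformly sampled 1D physiological signal.

    Sample ``i`` lives at time ``t0 + i / fs`` seconds.
    """

    samples: np.ndarray
    fs: float
    units: str = "arbitrary"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs a 1D array of at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.units not in VALID_UNITS:
            raise UnitError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (len(self) - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def copy(self, **changes) -> "Trace":
        out = replace(self, **changes)
        if "samples" not in changes:
            out.samples = self.samples.copy()
        return out


@dataclass
class TaskTiming:
    """Breath-hold task structure: one row of timestamps per trial.

    Each trial is (paced_start, hold_start, hold_end, recovery_end) in
    seconds; ``skipped`` marks trials where the hold was intentionally
    replaced with rest (the hold window then brackets where the hold would
    have been).
    """

    trials: list[tuple[float, float, float, float]]
    skipped: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.skipped:
            self.skipped = [False] * len(self.trials)
        if len(self.skipped) != len(self.trials):
            raise ValueError("skipped flags must match number of trials")
        prev_end = -np.inf
        for i, (ps, hs, he, re_) in enumerate(self.trials):
            if not (ps < hs <= he <= re_):
                if not (self.skipped[i] and ps < hs <= he <= re_):
                    raise ValueError(f"trial {i} timestamps not increasing: {(ps, hs, he, re_)}")
            if ps < prev_end:
                raise ValueError(f"trial {i} overlaps the previous trial")
            prev_end = re_

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def hold_starts(self) -> np.ndarray:
        return np.array([t[1] for t in self.trials])

    @property
    def hold_ends(self) -> np.ndarray:
        return np.array([t[2] for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.trials, columns=["paced_start", "hold_start", "hold_end", "recovery_end"]
        )
        df["skipped"] = np.asarray(self.skipped, dtype=int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaskTiming":
        trials = [
            (float(r.paced_start), float(r.hold_start), float(r.hold_end), float(r.recovery_end))
            for r in df.itertuples()
        ]
        skipped = [bool(s) for s in df["skipped"]] if "skipped" in df else []
        return cls(trials=trials, skipped=skipped)


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".tsv.gz", ".tsv"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_physio(
    path: str | Path,
    sidecar: str | Path | None = None,
    *,
    fs: float | None = None,
    units: str = "arbitrary",
    column: str | int = 0,
) -> Trace:
    """Read a physiological trace from a (gzipped) TSV file.

    Sampling rate resolution order: explicit JSON sidecar, a sidecar sitting
    next to the file, then the ``fs`` keyword.  ``column`` selects a column
    by name (when the sidecar declares ``Columns``) or position.
    """
    path = Path(path)
    meta: dict = {}
    sidecar_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    rate = meta.get("SamplingFrequency", fs)
    if rate is None:
        raise PhysioConfigError(f"no sampling rate for {path}: provide a sidecar or fs=")
    t0 = float(meta.get("StartTime", 0.0))
    columns = meta.get("Columns")

    with _open_maybe_gz(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str, comment="#")
    # a header row of labels is allowed; detect it as an all-non-numeric first row
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    header_rows = 0
    if first.isna().all():
        if columns is None:
            columns = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
        header_rows = 1
    if isinstance(column, str):
        if columns is None or column not in columns:
            raise PhysioConfigError(f"column {column!r} not declared for {path}")
        col_idx = list(columns).index(column)
    else:
        col_idx = int(column)
    raw = df.iloc[:, col_idx]
    values = pd.to_numeric(raw, errors="coerce")
    bad = np.flatnonzero(values.isna().to_numpy())
    if bad.size:
        row = int(bad[0]) + header_rows
        raise PhysioParseError(f"non-numeric value {raw.iloc[bad[0]]!r} at row {row} of {path}")
    return Trace(values.to_numpy(dtype=float), fs=float(rate), units=meta.get("Units", units), t0=t0)


def write_physio(trace: Trace, path: str | Path, columns: Sequence[str] = ("signal",)) -> Path:
    """Write a trace as TSV (+ JSON sidecar). Returns the sidecar path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _open_maybe_gz(path, "wt") as fh:
        for v in trace.samples:
            fh.write(f"{v:.12g}\n")
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "SamplingFrequency": trace.fs,
                "StartTime": trace.t0,
                "Columns": list(columns),
                "Units": trace.units,
            },
            fh,
            indent=1,
        )
    return sidecar


def volts_to_mmhg(trace: Trace, gain: float, offset: float = 0.0) -> Trace:
    """Linear gas-analyzer calibration: mmHg = gain * volts + offset."""
    if trace.units != "volts":
        raise UnitError(f"expected a trace in volts, got {trace.units}")
    if not gain > 0:
        raise ValueError("gain must be positive")
    return trace.copy(samples=gain * trace.samples + offset, units="mmHg")


def resample(trace: Trace, fs_out: float) -> Trace:
    """Resample to ``fs_out`` by linear interpolation on the time grid.

    End-tidal and RVT series are themselves piecewise-linear interpolations
    of sparse breath-wise points, so linear resampling adds no new extrema.
    """
    if not fs_out > 0:
        raise ValueError("fs_out must be positive")
    if fs_out == trace.fs:
        return trace.copy()
    n_out = int(np.floor(trace.duration * fs_out)) + 1
    t_new = trace.t0 + np.arange(n_out) / fs_out
    out = np.interp(t_new, trace.times(), trace.samples)
    return trace.copy(samples=out, fs=fs_out)


# --- volumetric I/O -------------------------------------------------------

def read_nifti(path: str | Path):
    """Return (data array, nibabel image) for a NIfTI file."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img


def write_nifti(data: np.ndarray, path: str | Path, like=None, affine=None) -> None:
    import nibabel as nib

    if affine is None:
        affine = like.affine if like is not None else np.eye(4)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine).to_filename(str(path))
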