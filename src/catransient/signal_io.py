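"""Plain-text I/O for Ca2+ transient signals and derived tables.

A *signal* is one cell's uniformly sampled Fura-2 340/380 nm ratio trace.
Sample timestamps are implicit: ``t = index / fs``.  Signals travel as a
long-format CSV (``signal_id,sample_index,value``) plus a sidecar manifest
CSV (``signal_id,fs,label``) holding per-signal metadata; a wide format
(one column per signal) is supported for reading short equal-length traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Disease / control classes of the study.
CLASS_LABELS: tuple[str, ...] = ("LQT1", "HCM", "CPVT", "WT")
ALLOWED_LABELS: tuple[str, ...] = CLASS_LABELS + ("UNKNOWN",)

#: Fixed column order for feature tables (the ten peak variables).
FEATURE_COLUMNS: tuple[str, ...] = (
    "A_l", "A_r", "D_l", "D_r",
    "max_d1", "abs_min_d1", "max_d2", "abs_min_d2",
    "R", "delta",
)


@dataclass
class Signal:
    """One cell's Ca2+ transient recording.

    Parameters
    ----------
    id : str
        Unique identifier of the recording (one recording = one cell).
    samples : array-like of float
        Fluorescence ratio values, arbitrary units, uniformly sampled.
    fs : float
        Sampling frequency in Hz (study regimes: ~8.3, 11 or 23).
    label : str
        Class label, one of ``ALLOWED_LABELS``.
    """

    id: str
    samples: np.ndarray
    fs: float
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError(
                f"signal {self.id!r}: need a 1-D trace with >= 2 samples"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"signal {self.id!r}: samples must be finite")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"signal {self.id!r}: fs must be positive, got {self.fs}")
        if self.label not in ALLOWED_LABELS:
            raise ValueError(
                f"signal {self.id!r}: unknown label {self.label!r}; "
                f"allowed: {set(ALLOWED_LABELS)}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (index / fs)."""
        return np.arange(self.samples.size) / self.fs


def manifest_path_for(path: Path | str) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".manifest.csv")


def _read_manifest(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    man = pd.read_csv(path, dtype={"signal_id": str})
    for col in ("signal_id", "fs", "label"):
        if col not in man.columns:
            raise ValueError(f"manifest {path}: missing column {col!r}")
    return man.set_index("signal_id")


def _lookup_meta(man: pd.DataFrame, sid: str) -> tuple[float, str]:
    if sid not in man.index:
        raise ValueError(f"signal {sid!r}: no fs/label entry in manifest")
    row = man.loc[sid]
    fs = row["fs"]
    if pd.isna(fs):
        raise ValueError(f"signal {sid!r}: missing fs in manifest")
    label = str(row["label"])
    if label not in ALLOWED_LABELS:
        raise ValueError(
            f"signal {sid!r}: unknown label {label!r}; allowed: {set(ALLOWED_LABELS)}"
        )
    return float(fs), label


def read_signals(
    path: Path | str,
    format: str = "csv-long",
    manifest: Path | str | None = None,
) -> list[Signal]:
    """Read signals from CSV, attaching fs and label from the manifest.

    ``csv-long`` expects columns ``signal_id,sample_index,value``; sample
    order follows ``sample_index``.  ``csv-wide`` expects one column per
    signal (column name = signal id).  Raises with the offending signal id
    or row number on malformed input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    man = _read_manifest(Path(manifest) if manifest else manifest_path_for(path))

    signals: list[Signal] = []
    if format == "csv-long":
        df = pd.read_csv(path, dtype={"signal_id": str}, float_precision="round_trip")
        for col in ("signal_id", "sample_index", "value"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            # +2: one for the header row, one for 0- vs 1-based counting
            raise ValueError(
                f"{path}: non-numeric sample value at row {bad[0] + 2}"
            )
        df = df.assign(value=values)
        # groupby(sort=False) preserves first-appearance order of signals
        for sid, grp in df.groupby("signal_id", sort=False):
            grp = grp.sort_values("sample_index", kind="stable")
            fs, label = _lookup_meta(man, str(sid))
            signals.append(Signal(str(sid), grp["value"].to_numpy(), fs, label))
    elif format == "csv-wide":
        df = pd.read_csv(path, float_precision="round_trip")
        for sid in df.columns:
            col = pd.to_numeric(df[sid], errors="coerce")
            bad = np.flatnonzero(col.isna().to_numpy() & df[sid].notna().to_numpy())
            if bad.size:
                raise ValueError(
                    f"{path}: non-numeric sample value at row {bad[0] + 2} "
                    f"(signal {sid!r})"
                )
            fs, label = _lookup_meta(man, str(sid))
            signals.append(Signal(str(sid), col.dropna().to_numpy(), fs, label))
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv-long' or 'csv-wide'")
    return signals


def write_signals(signals: Iterable[Signal], path: Path | str) -> None:
    """Write signals as csv-long plus a sidecar manifest.

    Round-trips through :func:`read_signals` at full float precision.
    """
    path = Path(path)
    signals = list(signals)
    rows = {
        "signal_id": np.concatenate(
            [np.repeat(s.id, s.n_samples) for s in signals]
        ) if signals else np.array([], dtype=str),
        "sample_index": np.concatenate(
            [np.arange(s.n_samples) for s in signals]
        ) if signals else np.array([], dtype=int),
        "value": np.concatenate([s.samples for s in signals])
        if signals else np.array([], dtype=float),
    }
    try:
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
        pd.DataFrame(
            {
                "signal_id": [s.id for s in signals],
                "fs": [s.fs for s in signals],
                "label": [s.label for s in signals],
            }
        ).to_csv(manifest_path_for(path), index=False, float_format="%.17g")
    except OSError as exc:  # pragma: no cover - env dependent
        raise OSError(f"failed writing signals to {path}: {exc}") from exc


def write_feature_table(table: pd.DataFrame, path: Path | str) -> None:
    """Write a feature table (one row per signal or per peak) as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: Path | str) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"signal_id": str}, float_precision="round_trip")
    if "abnormal" in df.columns:
        df["abnormal"] = df["abnormal"].astype(bool)
    return df
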