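"""The ten per-peak morphology variables of a Ca2+ transient.

For a delineated peak with beginning ``a``, top ``c`` and end ``g`` (sample
indices, ``a < c < g``) of a signal ``s`` sampled at frequency ``F``:

* ``A_l = s(c) - s(a)``, ``A_r = s(c) - s(g)`` — side amplitudes,
* ``D_l = (c - a)/F``, ``D_r = (g - c)/F`` — side durations (s),
* ``max_d1`` — maximum of s' on the rising side [a, c] (at landmark b),
* ``abs_min_d1`` — |minimum| of s' on the falling side [c, g] (at e),
* ``max_d2`` / ``abs_min_d2`` — maximum / |minimum| of s'' on the falling
  side [c, g] (at landmarks f and d),
* ``R`` — trapezoidal area between the curve and the chord from
  (a, s(a)) to (g, s(g)),
* ``delta`` — peak-to-peak interval: top-to-top time for the 2nd peak on,
  and time from the signal beginning to the first top for the first peak.

Derivatives use first central differences scaled by ``F`` (one-sided at
segment ends); all ten variables are invariant to a constant baseline
offset, and the non-temporal ones scale linearly with the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import FEATURE_COLUMNS, Signal

logger = logging.getLogger(__name__)


@dataclass
class PeakVariables:
    """The ten-variable morphology vector of a single peak."""

    A_l: float
    A_r: float
    D_l: float
    D_r: float
    max_d1: float
    abs_min_d1: float
    max_d2: float
    abs_min_d2: float
    R: float
    delta: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}


def compute_amplitudes(samples: np.ndarray, a: int, c: int, g: int) -> tuple[float, float]:
    """Side amplitudes ``A_l = s(c) - s(a)`` and ``A_r = s(c) - s(g)``."""
    s = np.asarray(samples, dtype=float)
    return float(s[c] - s[a]), float(s[c] - s[g])


def compute_durations(a: int, c: int, g: int, fs: float) -> tuple[float, float]:
    """Side durations ``D_l = (c - a)/F`` and ``D_r = (g - c)/F`` in seconds."""
    return (c - a) / fs, (g - c) / fs


def _central_diff(values: np.ndarray, fs: float) -> np.ndarray:
    """First derivative by central differences, one-sided at the ends."""
    return np.gradient(values, 1.0 / fs, edge_order=1)


def compute_derivative_extrema(
    samples: np.ndarray, a: int, c: int, g: int, fs: float
) -> tuple[float, float, float, float, int, int, int, int]:
    """First/second-derivative extrema and their landmark indices.

    Returns ``(max_d1, abs_min_d1, max_d2, abs_min_d2, b, e, d, f)`` where
    ``b`` is the index of max s' on [a, c], ``e`` of min s' on [c, g], and
    ``d`` / ``f`` of the min / max of s'' on the falling segment [c, g].
    Indices refer to the parent signal.
    """
    if c - a < 2 or g - c < 2:
        raise ValueError(
            f"peak (a={a}, c={c}, g={g}): each side needs >= 3 samples "
            "for the derivative stencil"
        )
    s = np.asarray(samples, dtype=float)[a : g + 1]
    d1 = _central_diff(s, fs)
    d2 = _central_diff(d1, fs)

    left = d1[: c - a + 1]
    right1 = d1[c - a :]
    b = a + int(np.argmax(left))
    e = c + int(np.argmin(right1))
    right2 = d2[c - a :]
    d_idx = c + int(np.argmin(right2))
    f_idx = c + int(np.argmax(right2))
    return (
        float(np.max(left)),
        float(abs(np.min(right1))),
        float(np.max(right2)),
        float(abs(np.min(right2))),
        b, e, d_idx, f_idx,
    )


def compute_area(
    samples: np.ndarray, a: int, c: int, g: int, fs: float, mode: str = "chord"
) -> float:
    """Trapezoidal peak area ``R``.

    ``mode="chord"`` (default) integrates the curve over [a, g] and
    subtracts the trapezoid under the straight chord from (a, s(a)) to
    (g, s(g)) — the area enclosed by the curve and the chord.
    ``mode="strict"`` subtracts only ``(g - a) * s(g) / (2F)``, a literal
    rendering of the printed summation that coincides with the chord
    correction when ``s(a) = s(g)``.  A curve dipping below the chord
    contributes negatively.
    """
    s = np.asarray(samples, dtype=float)[a : g + 1]
    curve = float(np.trapezoid(s, dx=1.0 / fs))
    if mode == "chord":
        correction = (g - a) * (s[0] + s[-1]) / (2.0 * fs)
    elif mode == "strict":
        correction = (g - a) * s[-1] / (2.0 * fs)
    else:
        raise ValueError(f"unknown area mode {mode!r}; use 'chord' or 'strict'")
    return curve - float(correction)


def compute_delta(peak_tops: np.ndarray, fs: float) -> np.ndarray:
    """Peak-to-peak intervals in seconds for tops ordered in time.

    The first peak's interval is measured from the signal beginning to its
    top; every later interval is top-to-top.
    """
    tops = np.asarray(peak_tops, dtype=float)
    if tops.size == 0:
        return np.array([])
    deltas = np.empty(tops.size)
    deltas[0] = tops[0] / fs
    deltas[1:] = np.diff(tops) / fs
    return deltas


def peak_variables(
    signal: Signal, peaks: "list", area_mode: str = "chord"
) -> list[PeakVariables]:
    """Compute the ten variables for every peak of one signal.

    ``peaks`` is an ordered list of objects with integer ``a, c, g``
    attributes (see :mod:`catransient.peaks`).
    """
    deltas = compute_delta(np.array([p.c for p in peaks]), signal.fs)
    out = []
    for p, delta in zip(peaks, deltas):
        A_l, A_r = compute_amplitudes(signal.samples, p.a, p.c, p.g)
        D_l, D_r = compute_durations(p.a, p.c, p.g, signal.fs)
        max_d1, abs_min_d1, max_d2, abs_min_d2, *_ = compute_derivative_extrema(
            signal.samples, p.a, p.c, p.g, signal.fs
        )
        R = compute_area(signal.samples, p.a, p.c, p.g, signal.fs, mode=area_mode)
        out.append(
            PeakVariables(A_l, A_r, D_l, D_r, max_d1, abs_min_d1,
                          max_d2, abs_min_d2, R, delta)
        )
    return out


def build_feature_table(
    signals: "list[Signal]",
    annotations: "list",
    aggregation: str = "mean",
    include_abnormal_peaks: bool = True,
    area_mode: str = "chord",
) -> pd.DataFrame:
    """Aggregate per-peak variables into the classification feature table.

    One row per signal (``aggregation="mean"``: 10 columns;
    ``"mean_sd"``: 20, adding per-variable SDs) or one row per peak
    (``"per_peak"``).  Every row carries ``signal_id``, ``label`` and the
    signal-level ``abnormal`` stratum.  Peaks truncated by the recording
    edge never contribute; signals left with no usable peak are dropped
    with a logged warning.  ``include_abnormal_peaks=False`` additionally
    restricts to peaks labeled normal.
    """
    if aggregation not in ("mean", "mean_sd", "per_peak"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    ann_by_id = {ann.signal_id: ann for ann in annotations}
    rows: list[dict] = []
    for sig in signals:
        ann = ann_by_id.get(sig.id)
        if ann is None or not ann.peaks:
            logger.warning("signal %s: no peaks; excluded from feature table", sig.id)
            continue
        kept = [p for p in ann.peaks if not getattr(p, "truncated", False)]
        if not include_abnormal_peaks:
            kept = [p for p in kept if not p.abnormal]
        if not kept:
            logger.warning("signal %s: no usable peaks; excluded", sig.id)
            continue
        pv = peak_variables(sig, kept, area_mode=area_mode)
        meta = {"signal_id": sig.id, "label": sig.label,
                "abnormal": ann.signal_abnormal}
        if aggregation == "per_peak":
            for i, (p, v) in enumerate(zip(kept, pv)):
                rows.append({**meta, "peak_index": i,
                             "peak_abnormal": p.abnormal, **v.as_dict()})
        else:
            mat = np.array([[getattr(v, name) for name in FEATURE_COLUMNS]
                            for v in pv])
            row = {**meta, "n_peaks": len(pv)}
            row.update(dict(zip(FEATURE_COLUMNS, mat.mean(axis=0))))
            if aggregation == "mean_sd":
                row.update({f"{name}_sd": sd for name, sd in
                            zip(FEATURE_COLUMNS, mat.std(axis=0, ddof=0))})
            rows.append(row)
    return pd.DataFrame(rows)
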