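"""Peak delineation and normal/abnormal labeling of Ca2+ transients.

Each transient peak is delineated by three landmarks: beginning ``a``
(last pre-rise local minimum), top ``c`` (maximum) and end ``g``
(post-decay local minimum or the next peak's onset).  Candidate maxima
whose amplitude falls below 2 % of the largest peak amplitude within the
same signal are discarded as noise blips; the 2 % reference is always
per-signal, never global.

Peaks are labeled abnormal by a three-rule morphology heuristic mirroring
the visually described motifs (small peaks, left/right amplitude
asymmetry, deformed shapes); a signal is abnormal iff at least one of its
peaks is abnormal.  Per-peak labels may instead be supplied externally
(e.g. an expert's annotation CSV) via ``annotate_signal(..., labels=...)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .features import compute_amplitudes
from .signal_io import Signal

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    """One delineated transient: landmark sample indices and its label.

    ``a <= b <= c <= e <= g`` with ``d, f`` in ``[c, g]``; ``b, e`` are
    first-derivative extrema landmarks and ``d, f`` second-derivative ones
    (filled in by the feature stage when requested).  ``truncated`` marks a
    peak whose rise or decay hits a recording edge; such peaks are kept in
    the annotation but excluded from feature tables.
    """

    a: int
    c: int
    g: int
    abnormal: bool = False
    truncated: bool = False
    b: int | None = None
    e: int | None = None
    d: int | None = None
    f: int | None = None

    def __post_init__(self) -> None:
        if not (self.a < self.c < self.g):
            raise ValueError(f"invalid peak landmarks a={self.a} c={self.c} g={self.g}")


@dataclass
class SignalAnnotation:
    """All peaks of one signal plus the signal-level abnormality flag."""

    signal_id: str
    peaks: list[Peak] = field(default_factory=list)

    @property
    def signal_abnormal(self) -> bool:
        """A signal is abnormal iff any of its peaks is abnormal."""
        return any(p.abnormal for p in self.peaks)


@dataclass
class DetectionParams:
    """Tunable thresholds of the delineation + labeling heuristic.

    min_prominence_frac
        Noise floor: retain peaks with amplitude >= this fraction of the
        largest peak amplitude in the signal (the 2 % rule).
    smooth_window_s
        Moving-average width (seconds) applied before delineation.
    merge_valley_frac
        Adjacent candidate maxima separated by a valley higher than this
        fraction of the lower maximum's height above baseline are merged
        into one peak (a shoulder on a decay is a deformity, not a new
        transient).
    small_peak_frac, asym_frac, deform_frac
        Abnormality rules: a peak is abnormal if its amplitude is below
        ``small_peak_frac`` of the in-signal maximum, or
        ``|A_l - A_r| / max(A_l, A_r)`` exceeds ``asym_frac``, or a
        secondary local maximum inside [a, g] has prominence above
        ``deform_frac`` of the peak amplitude.
    """

    min_prominence_frac: float = 0.02
    smooth_window_s: float = 0.1
    merge_valley_frac: float = 0.4
    small_peak_frac: float = 0.30
    asym_frac: float = 0.40
    deform_frac: float = 0.15


def _smooth(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    w = int(round(window_s * fs))
    if w % 2 == 0:
        w += 1
    if w < 3:
        return x.astype(float)
    return uniform_filter1d(x.astype(float), size=w, mode="nearest")


def _noise_floor(x: np.ndarray, xs: np.ndarray, w: int) -> float:
    """Noise SD of the smoothed trace, estimated on quiet samples only.

    Peak flanks dominate successive differences in a peak-dense signal, so
    the estimate is restricted to samples near the baseline (lowest
    quartile of the smoothed trace); the raw-sample SD is then scaled by
    the averaging window.
    """
    quiet = xs <= np.percentile(xs, 25)
    d = np.diff(x)[quiet[:-1] & quiet[1:]]
    if d.size < 4:
        d = np.diff(x)
    if d.size == 0:
        return 0.0
    sigma_raw = 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)
    return sigma_raw / np.sqrt(max(w, 1))


def _walk_right(xs: np.ndarray, start: int, limit: int, tol: float, patience: int) -> int:
    """Descend from ``start`` to the peak foot.

    Moves to the minimum of a short lookahead window as long as that
    minimum undercuts the current level by more than the noise tolerance;
    stops otherwise, so a flat (or plateaued) tail is not overrun.
    """
    i = start
    while i < limit:
        hi = min(i + patience, limit)
        j = i + 1 + int(np.argmin(xs[i + 1 : hi + 1]))
        if xs[j] < xs[i] - tol:
            i = j
        else:
            break
    return i


def _walk_left(xs: np.ndarray, start: int, limit: int, tol: float, patience: int) -> int:
    i = start
    while i > limit:
        lo = max(i - patience, limit)
        j = lo + int(np.argmin(xs[lo:i]))
        if xs[j] < xs[i] - tol:
            i = j
        else:
            break
    return i


def _refine_foot_right(xs, origin: int, g0: int, limit: int, tol: float,
                       patience: int) -> int:
    """Snap the right boundary to the first crossing of the foot level.

    ``g0`` is the walk's stop point; the foot level is a robust low
    quantile of the window beyond it.  Scanning the descent from
    ``origin`` for the first sample within ``tol`` of that level is
    robust both to the walk stopping early on a shallow foot and to
    overrunning into baseline.
    """
    hi = min(limit, g0 + 2 * patience)
    if hi <= g0:
        return g0
    # a low percentile tracks the quiet level even when the window clips
    # the next peak's rise, without being dragged down by noise dips
    level = float(np.percentile(xs[g0 : hi + 1], 30))
    for j in range(origin + 1, hi + 1):
        if xs[j] <= level + tol:
            return j
    return g0


def _refine_foot_left(xs, origin: int, a0: int, limit: int, tol: float,
                      patience: int) -> int:
    lo = max(limit, a0 - 2 * patience)
    if lo >= a0:
        return a0
    level = float(np.percentile(xs[lo : a0 + 1], 30))
    for j in range(origin - 1, lo - 1, -1):
        if xs[j] <= level + tol:
            return j
    return a0


def _merge_candidates(
    xs: np.ndarray, cands: np.ndarray, base: float, frac: float
) -> list[list[int]]:
    """Group adjacent maxima separated by a shallow valley into one peak.

    A shoulder or notch on a flank shows up as a secondary maximum whose
    separating valley stays high above baseline; it belongs to the same
    transient (a deformity), not a new one.  Returns ordered groups of
    candidate indices; each group becomes a single peak whose boundaries
    are walked out from the group's outermost members.
    """
    groups: list[list[int]] = [[int(c)] for c in cands]
    changed = True
    while changed and len(groups) > 1:
        changed = False
        for i in range(len(groups) - 1):
            p = max(groups[i], key=lambda k: xs[k])
            q = max(groups[i + 1], key=lambda k: xs[k])
            valley = xs[p : q + 1].min()
            lower_height = min(xs[p], xs[q]) - base
            if lower_height > 0 and (valley - base) > frac * lower_height:
                groups[i] = sorted(groups[i] + groups[i + 1])
                groups.pop(i + 1)
                changed = True
                break
    return groups


def detect_peaks(signal: Signal, params: DetectionParams | None = None) -> SignalAnnotation:
    """Delineate peaks (a, c, g) of one signal; no abnormality labels yet.

    Deterministic and idempotent: smoothing -> candidate maxima ->
    shoulder merging -> boundary walk-out -> per-signal 2 % amplitude
    filter.  A flat or monotone trace yields an empty annotation; NaNs are
    an error.
    """
    params = params or DetectionParams()
    x = np.asarray(signal.samples, dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"signal {signal.id!r}: NaN samples")
    xs = _smooth(x, signal.fs, params.smooth_window_s)

    w = int(round(params.smooth_window_s * signal.fs))
    w = max(1, w + 1 if w % 2 == 0 else w)
    sigma = _noise_floor(x, xs, w)
    tol = 3.0 * sigma

    # candidates must clear the noise floor; sub-noise wiggles would
    # otherwise be grouped into real peaks and corrupt their boundaries
    cands, _ = find_peaks(xs, prominence=max(5.0 * sigma, 1e-12))
    if cands.size == 0:
        return SignalAnnotation(signal.id, [])
    base = float(np.percentile(xs, 10))
    groups = _merge_candidates(xs, cands, base, params.merge_valley_frac)

    # boundary walk-out on the smoothed trace, top refined on the raw one
    half = max(1, w // 2 + 1)
    patience = max(2, int(round(0.13 * signal.fs)))
    peaks: list[Peak] = []
    for i, grp in enumerate(groups):
        c = max(grp, key=lambda k: xs[k])
        left_limit = int(max(groups[i - 1])) if i > 0 else 0
        right_limit = int(min(groups[i + 1])) if i < len(groups) - 1 else len(xs) - 1
        a0 = _walk_left(xs, int(min(grp)), left_limit, tol, patience)
        g0 = _walk_right(xs, int(max(grp)), right_limit, tol, patience)
        a = _refine_foot_left(xs, int(min(grp)), a0, left_limit, tol, patience)
        g = _refine_foot_right(xs, int(max(grp)), g0, right_limit, tol, patience)
        if not (a < c < g):
            continue  # no real descent on one side: not a transient
        lo, hi = max(a + 1, c - half), min(g, c + half + 1)
        c_raw = lo + int(np.argmax(x[lo:hi]))
        if not (a < c_raw < g):
            continue
        # smoothing spreads the rise onset leftward; snap a forward on the
        # raw trace while it still sits at baseline level
        tol_raw = tol * np.sqrt(w)
        lvl = float(np.median(x[max(left_limit, a - 3) : a + 1]))
        while a + 1 < c_raw and x[a + 1] <= lvl + tol_raw:
            a += 1
        if c_raw - a < 2 or g - c_raw < 2:
            continue  # min-duration rule: each side needs >= 2 intervals
        truncated = (a == 0 and xs[0] < xs[c]) or (g == len(xs) - 1 and xs[-1] < xs[c])
        peaks.append(Peak(a, c_raw, g, truncated=truncated))

    if not peaks:
        return SignalAnnotation(signal.id, [])
    # adjacent peaks may share a valley but never overlap
    for i in range(len(peaks) - 1):
        if peaks[i].g > peaks[i + 1].a and peaks[i + 1].a >= peaks[i].c + 2:
            peaks[i] = replace(peaks[i], g=peaks[i + 1].a)
    amps = np.array([_peak_amplitude(x, p) for p in peaks])
    keep = amps >= params.min_prominence_frac * amps.max()
    retained = [p for p, k in zip(peaks, keep) if k]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("signal %s: dropped %d sub-noise-floor blips", signal.id, n_dropped)
    return SignalAnnotation(signal.id, retained)


def _peak_amplitude(x: np.ndarray, p: Peak) -> float:
    A_l, A_r = compute_amplitudes(x, p.a, p.c, p.g)
    return max(A_l, A_r)


def _secondary_max_prominence(x: np.ndarray, p: Peak) -> float:
    """Largest prominence of a local maximum inside (a, g) other than the top.

    Prominence is measured down to the valley separating the secondary
    maximum from the main top.
    """
    seg = x[p.a : p.g + 1]
    c_rel = p.c - p.a
    locs, _ = find_peaks(seg)
    best = 0.0
    for m in locs:
        if m == c_rel:
            continue
        lo, hi = (m, c_rel) if m < c_rel else (c_rel, m)
        valley = seg[lo : hi + 1].min()
        best = max(best, float(seg[m] - valley))
    return best


def classify_peak(
    peak: Peak,
    signal: Signal,
    max_amplitude: float,
    params: DetectionParams | None = None,
) -> bool:
    """Label one peak abnormal if any of the three morphology rules fires.

    ``max_amplitude`` is the largest peak amplitude within the same signal
    (the rules are always relative to the signal's own peaks).
    """
    params = params or DetectionParams()
    x = np.asarray(signal.samples, dtype=float)
    A_l, A_r = compute_amplitudes(x, peak.a, peak.c, peak.g)
    amp = max(A_l, A_r)
    if amp <= 0:
        return True
    if max_amplitude > 0 and amp < params.small_peak_frac * max_amplitude:
        return True
    if abs(A_l - A_r) / amp > params.asym_frac:
        return True
    if _secondary_max_prominence(x, peak) > params.deform_frac * amp:
        return True
    return False


def annotate_signal(
    signal: Signal,
    params: DetectionParams | None = None,
    labels: "dict[int, bool] | None" = None,
) -> SignalAnnotation:
    """Delineate and label all peaks of one signal.

    ``labels`` optionally supplies externally determined per-peak
    normal/abnormal flags (keyed by peak position in detection order),
    overriding the heuristic — the workflow used when an expert's labels
    exist.  An empty peak list yields ``signal_abnormal == False`` with a
    logged warning.
    """
    params = params or DetectionParams()
    ann = detect_peaks(signal, params)
    if not ann.peaks:
        logger.warning("signal %s: no peaks detected", signal.id)
        return ann
    x = np.asarray(signal.samples, dtype=float)
    max_amp = max(_peak_amplitude(x, p) for p in ann.peaks)
    labeled = []
    for i, p in enumerate(ann.peaks):
        if labels is not None and i in labels:
            flag = bool(labels[i])
        else:
            flag = classify_peak(p, signal, max_amp, params)
        labeled.append(replace(p, abnormal=flag))
    return SignalAnnotation(signal.id, labeled)


def annotations_to_frame(annotations: list[SignalAnnotation]):
    """Flatten annotations to the ground-truth-compatible CSV schema."""
    import pandas as pd

    rows = [
        {"signal_id": ann.signal_id, "peak_index": i,
         "a": p.a, "c": p.c, "g": p.g,
         "abnormal": p.abnormal, "truncated": p.truncated}
        for ann in annotations
        for i, p in enumerate(ann.peaks)
    ]
    return pd.DataFrame(
        rows, columns=["signal_id", "peak_index", "a", "c", "g", "abnormal", "truncated"]
    )
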