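"""Temporal features of synergy activation coefficients.

Each activation curve (one synergy's recruitment over the BON-100 ms to
TD+100 ms window) is first time-normalized to 100 points so participants
with different step durations are comparable. Features: peak amplitude,
time of peak (percent of span, first index on ties), area under the curve
(trapezoidal, on the normalized 0..100 percent axis), and activation onset
(first point strictly exceeding 25% of the peak, as percent of span; an
all-zero curve has no onset and the pair is dropped from onset statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import stats as sstats

__all__ = [
    "ActivationFeatures",
    "time_normalize",
    "onset",
    "peak_and_area",
    "extract_features",
    "compare_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("peak_amp", "area", "peak_time_pct", "onset_pct")


@dataclass
class ActivationFeatures:
    peak_amp: float
    area: float
    peak_time_pct: float
    onset_pct: Optional[float]      # None when the curve never crosses threshold
    curve100: np.ndarray

    def __post_init__(self) -> None:
        if self.onset_pct is not None and not (
            0.0 <= self.onset_pct <= self.peak_time_pct <= 100.0
        ):
            raise ValueError("onset must precede the peak within the span")


def time_normalize(c: Sequence[float], n_out: int = 100) -> np.ndarray:
    """Linearly resample a curve onto ``n_out`` equally spaced points.

    The output spans the full duration with endpoints preserved; a
    length-100 input passes through unchanged.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValueError("activation curve needs at least 2 samples")
    src = np.linspace(0.0, 1.0, c.size)
    dst = np.linspace(0.0, 1.0, n_out)
    return np.interp(dst, src, c)


def onset(curve100: np.ndarray, frac_pct: float = 25.0) -> Optional[float]:
    """Onset: first point strictly above ``frac_pct`` percent of the peak.

    Returned as percent of the span. A curve that already exceeds the
    threshold at its first point has onset 0; an all-zero curve has no
    onset and returns None.
    """
    c = np.asarray(curve100, dtype=float)
    peak = c.max()
    if peak <= 0:
        return None
    above = c > (frac_pct / 100.0) * peak
    if not above.any():
        return None
    idx = int(np.argmax(above))
    return 100.0 * idx / (c.size - 1)


def peak_and_area(curve100: np.ndarray) -> tuple[float, float, float]:
    """Peak amplitude, peak time (percent, first index on ties) and area.

    Area is the trapezoidal integral over the normalized time axis 0..100,
    so a constant curve of height h has area 100 h.
    """
    c = np.asarray(curve100, dtype=float)
    peak = float(c.max())
    peak_time = 100.0 * int(np.argmax(c)) / (c.size - 1)
    area = float(np.trapezoid(c, dx=100.0 / (c.size - 1)))
    return peak, peak_time, area


def extract_features(c: Sequence[float], n_out: int = 100,
                     onset_frac_pct: float = 25.0) -> ActivationFeatures:
    """Time-normalize an activation curve and compute all its features."""
    curve = time_normalize(c, n_out)
    peak, peak_time, area = peak_and_area(curve)
    on = onset(curve, onset_frac_pct)
    return ActivationFeatures(peak_amp=peak, area=area, peak_time_pct=peak_time,
                              onset_pct=on, curve100=curve)


def compare_features(early: Sequence[ActivationFeatures],
                     late: Sequence[ActivationFeatures]
                     ) -> dict[str, sstats.StatsResult]:
    """Paired t-tests on each feature between stages for one mode.

    ``early[i]`` and ``late[i]`` belong to the same participant. Pairs with
    an undefined onset in either stage are dropped from the onset test only.
    """
    if len(early) != len(late):
        raise ValueError("early/late feature lists must be paired")
    if len(early) < 3:
        raise ValueError("need at least 3 paired participants")
    out: dict[str, sstats.StatsResult] = {}
    for name in ("peak_amp", "area", "peak_time_pct"):
        e = [getattr(f, name) for f in early]
        l = [getattr(f, name) for f in late]
        out[name] = sstats.paired_t(e, l)
    pairs = [(f.onset_pct, g.onset_pct) for f, g in zip(early, late)
             if f.onset_pct is not None and g.onset_pct is not None]
    if len(pairs) >= 3:
        out["onset_pct"] = sstats.paired_t([p[0] for p in pairs],
                                           [p[1] for p in pairs])
    else:
        warnings.warn("fewer than 3 pairs with defined onsets; onset test skipped")
    return out
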