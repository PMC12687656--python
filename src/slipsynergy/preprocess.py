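"""EMG preprocessing: from raw signals to the activation matrix M.

The fixed chain is

    envelope -> window -> bin_average -> concatenate
             -> normalize_max -> scale_unit_variance

The envelope is a 35 Hz zero-phase high-pass, full-wave rectification, then
a 40 Hz zero-phase low-pass (second-order Butterworth per pass, applied
forward and backward, so effective fourth order with no phase lag). Each
trial is cut to the analysis window from 100 ms before belt onset (BON) to
100 ms after recovery-foot touchdown (TD), averaged into 10 ms bins, and the
two trials of a stage are concatenated end-to-end into an 8 x n matrix.
Rows are max-normalized (shared per-participant factors so early and late
stages stay comparable) and scaled to unit variance so every muscle weighs
equally in the factorization; the variance scales are stored so synergy
vectors can be mapped back to physiological scale afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .io_model import EmgTrial, MuscleChannel

__all__ = [
    "EnvelopeMatrix",
    "envelope",
    "window",
    "bin_average",
    "concatenate",
    "normalize_max",
    "scale_unit_variance",
    "session_norm_factors",
]


@dataclass
class EnvelopeMatrix:
    """Binned, non-negative muscle-by-timebin activation matrix."""

    values: np.ndarray                      # [8 x n_bins], >= 0
    bin_ms: float
    muscle_order: tuple[MuscleChannel, ...]
    trial_boundaries: list[int] = field(default_factory=lambda: [0])
    norm_factors: Optional[np.ndarray] = None       # per-muscle max divisors
    unit_var_scales: Optional[np.ndarray] = None    # per-muscle sd divisors

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if np.any(self.values < 0):
            raise ValueError("activation matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def replace(self, **kwargs) -> "EnvelopeMatrix":
        return replace(self, **kwargs)


def _zero_phase_butter(x: np.ndarray, cutoff_hz: float, rate_hz: float,
                       btype: str, order: int = 2) -> np.ndarray:
    nyq = rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, cutoff_hz / nyq, btype=btype, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def envelope(trial: EmgTrial, hp_hz: float = 35.0, lp_hz: float = 40.0) -> EmgTrial:
    """Linear envelope: high-pass, full-wave rectify, low-pass, clip at 0.

    Both filters are order-2 Butterworth applied forward and backward
    (zero phase, effective order 4). Low-pass ringing can produce small
    negative excursions; these are clipped to zero because the downstream
    factorization requires non-negativity.
    """
    if trial.rate_hz <= 2 * max(hp_hz, lp_hz):
        raise ValueError("sampling rate must exceed twice the filter cutoffs")
    x = _zero_phase_butter(trial.signal, hp_hz, trial.rate_hz, "highpass")
    x = np.abs(x)
    x = _zero_phase_butter(x, lp_hz, trial.rate_hz, "lowpass")
    return trial.replace(signal=np.clip(x, 0.0, None))


def window(trial_env: EmgTrial, bon_s: float, td_s: float,
           pre_ms: float = 100.0, post_ms: float = 100.0) -> EmgTrial:
    """Cut the analysis window [BON - pre, TD + post).

    Start-inclusive, end-exclusive in sample index, so a 480 ms window at
    600 Hz yields exactly 288 samples.
    """
    if td_s <= bon_s:
        raise ValueError(f"touchdown ({td_s} s) must follow belt onset ({bon_s} s)")
    fs = trial_env.rate_hz
    t0 = bon_s - pre_ms / 1000.0
    t1 = td_s + post_ms / 1000.0
    if t0 < 0:
        raise ValueError(f"window start {t0:.4f} s precedes trial start")
    start = int(round(t0 * fs))
    n = int(np.floor((t1 - t0) * fs + 1e-9))
    if n < 1:
        raise ValueError("analysis window is empty")
    if start + n > trial_env.n_samples:
        overrun = (start + n) / fs - trial_env.n_samples / fs
        raise ValueError(f"window overruns trial end by {overrun:.4f} s")
    return trial_env.replace(signal=trial_env.signal[:, start:start + n])


def bin_average(trial_env: EmgTrial, bin_ms: float = 10.0) -> EnvelopeMatrix:
    """Down-sample by averaging samples into fixed-width time bins.

    A sample belongs to the bin its start time falls in; the trailing
    partial bin is dropped rather than padded.
    """
    fs = trial_env.rate_hz
    n = trial_env.n_samples
    bin_s = bin_ms / 1000.0
    duration = n / fs
    n_bins = int(np.floor(duration / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError("trial shorter than one bin")
    t = np.arange(n) / fs
    idx = np.floor(t / bin_s + 1e-9).astype(int)
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("bin width too small: some bins contain no samples")
    sums = np.vstack([
        np.bincount(idx[keep], weights=row[keep], minlength=n_bins)
        for row in trial_env.signal
    ])
    values = sums / counts
    return EnvelopeMatrix(values=np.clip(values, 0.0, None), bin_ms=bin_ms,
                          muscle_order=trial_env.channels)


def concatenate(stage_trials: Sequence[EnvelopeMatrix]) -> EnvelopeMatrix:
    """Append stage trials end-to-end, recording each trial's first bin."""
    if not stage_trials:
        raise ValueError("no trials to concatenate")
    first = stage_trials[0]
    for m in stage_trials[1:]:
        if m.muscle_order != first.muscle_order:
            raise ValueError("muscle order mismatch between trials")
        if m.bin_ms != first.bin_ms:
            raise ValueError("bin width mismatch between trials")
    boundaries, start = [], 0
    for m in stage_trials:
        boundaries.append(start)
        start += m.n_bins
    values = np.concatenate([m.values for m in stage_trials], axis=1)
    return EnvelopeMatrix(values=values, bin_ms=first.bin_ms,
                          muscle_order=first.muscle_order,
                          trial_boundaries=boundaries)


def session_norm_factors(all_trial_matrices: Sequence[EnvelopeMatrix]) -> np.ndarray:
    """Per-muscle maxima over every trial of the session (shared factors)."""
    stacked = np.concatenate([m.values for m in all_trial_matrices], axis=1)
    return stacked.max(axis=1)


def normalize_max(m: EnvelopeMatrix,
                  norm_factors: Optional[np.ndarray] = None) -> EnvelopeMatrix:
    """Divide each muscle row by its maximum activation.

    ``norm_factors`` are usually the session-wide per-muscle maxima
    (:func:`session_norm_factors`) so that the early- and late-stage blocks
    share a scale; by default the matrix's own row maxima are used.
    """
    factors = np.asarray(norm_factors if norm_factors is not None
                         else m.values.max(axis=1), dtype=float)
    if factors.shape != (m.values.shape[0],):
        raise ValueError("norm_factors must have one entry per muscle")
    zero = np.where(factors <= 0)[0]
    if zero.size:
        labels = [m.muscle_order[i].label for i in zero]
        raise ValueError(f"zero maximum activation for muscle(s): {', '.join(labels)}")
    return m.replace(values=m.values / factors[:, None], norm_factors=factors)


def scale_unit_variance(m: EnvelopeMatrix) -> EnvelopeMatrix:
    """Scale each muscle row to unit sample variance (n-1 denominator).

    The divisors are stored in ``unit_var_scales`` so the factorization's
    synergy vectors can later be returned to their original scaling.
    """
    sds = m.values.std(axis=1, ddof=1)
    # effectively-constant rows (sd at rounding level) are degenerate too
    zero = np.where(sds <= 1e-12 * np.maximum(np.abs(m.values).max(axis=1), 1e-300))[0]
    if zero.size:
        labels = [m.muscle_order[i].label for i in zero]
        raise ValueError(f"zero variance for muscle(s): {', '.join(labels)}")
    return m.replace(values=m.values / sds[:, None], unit_var_scales=sds)
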