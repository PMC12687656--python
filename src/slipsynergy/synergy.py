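"""Muscle-synergy extraction by non-negative matrix factorization.

The activation matrix M (8 muscles x n time bins) is modelled as a sum of a
small number of synergies, M = c1 w1 + c2 w2 + ... + cK wK + eps, i.e.
M ~ W C with W (8 x K) the fixed, time-invariant synergy vectors and C
(K x n) their time-varying recruitment coefficients, both non-negative.

Factorization uses Lee-Seung multiplicative updates on the Frobenius
objective ||M - WC||^2 with multiple random restarts. Goodness of fit is the
uncentered variance accounted for (VAF), computed globally and per muscle;
the number of synergies is the smallest K whose factorization (a) exceeds
90% global VAF, (b) exceeds 75% VAF for every muscle, and (c) gains no more
than 5 percentage points of mean per-muscle VAF by adding one further
synergy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocess import EnvelopeMatrix

__all__ = [
    "SynergySet",
    "DimensionalityError",
    "nnmf",
    "vaf_global",
    "vaf_muscle",
    "select_dimensionality",
    "unscale_and_normalize",
]

_EPS = 1e-12  # floor on factors: keeps multiplicative updates from absorbing zeros


@dataclass
class SynergySet:
    """One participant-stage factorization M ~ W C."""

    W: np.ndarray                   # [8 x K] synergy vectors (columns)
    C: np.ndarray                   # [K x n_bins] activation coefficients
    k: int
    vaf_global: float               # percent
    vaf_muscle: np.ndarray          # 8 percents
    residual: np.ndarray            # M - WC
    restarts_used: int
    seed: int
    objective: float = np.nan       # ||M - WC||_F^2 at convergence
    diagnostics: dict = field(default_factory=dict)   # e.g. VAF curve by K

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.W.shape[1] != self.k or self.C.shape[0] != self.k:
            raise ValueError("W/C shapes inconsistent with k")
        if np.any(self.W < 0) or np.any(self.C < 0):
            raise ValueError("W and C must be non-negative")


class DimensionalityError(RuntimeError):
    """No candidate K satisfied the VAF selection criteria."""

    def __init__(self, message: str, vaf_curve: dict):
        super().__init__(message)
        self.vaf_curve = vaf_curve


def _vaf_pct(m: np.ndarray, recon: np.ndarray) -> float:
    denom = float(np.sum(m * m))
    if denom == 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    return 100.0 * (1.0 - float(np.sum((m - recon) ** 2)) / denom)


def _vaf_rows(m: np.ndarray, recon: np.ndarray) -> np.ndarray:
    """Per-row VAF; an identically-zero row perfectly reconstructed is 100."""
    denom = np.sum(m * m, axis=1)
    resid = np.sum((m - recon) ** 2, axis=1)
    out = np.empty(m.shape[0])
    zero = denom == 0
    out[~zero] = 100.0 * (1.0 - resid[~zero] / denom[~zero])
    out[zero] = np.where(resid[zero] <= 1e-24, 100.0, -np.inf)
    return out


def _mu_factorize(m: np.ndarray, k: int, max_iter: int, tol: float,
                  rng: np.random.Generator, check_monotone: bool = False
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update run from a uniform-random start."""
    n_rows, n_cols = m.shape
    w = rng.uniform(_EPS, 1.0, size=(n_rows, k))
    c = rng.uniform(_EPS, 1.0, size=(k, n_cols))
    prev = float(np.sum((m - w @ c) ** 2))
    for _ in range(max_iter):
        c *= (w.T @ m) / np.maximum(w.T @ w @ c, _EPS)
        np.maximum(c, _EPS, out=c)
        w *= (m @ c.T) / np.maximum(w @ (c @ c.T), _EPS)
        np.maximum(w, _EPS, out=w)
        obj = float(np.sum((m - w @ c) ** 2))
        if check_monotone and obj > prev * (1 + 1e-9) + 1e-12:
            raise AssertionError("multiplicative update increased the objective")
        if prev - obj < tol * max(prev, _EPS):
            prev = obj
            break
        prev = obj
    return w, c, prev


def nnmf(m: EnvelopeMatrix | np.ndarray, k: int, restarts: int = 20,
         max_iter: int = 2000, tol: float = 1e-6, seed: int = 0,
         check_monotone: bool = False) -> SynergySet:
    """Best-of-restarts non-negative factorization at fixed K.

    Deterministic given ``seed``: each restart draws its initial W, C from an
    independent substream of one seeded generator, and the run with the
    lowest residual norm wins.
    """
    values = m.values if isinstance(m, EnvelopeMatrix) else np.asarray(m, dtype=float)
    if np.any(values < 0):
        raise ValueError("input matrix must be non-negative")
    if not np.any(values > 0):
        raise ValueError("input matrix is all zero")
    n_rows, n_cols = values.shape
    if not (1 <= k <= min(n_rows, n_cols)):
        raise ValueError(f"k={k} outside 1..min{values.shape}")

    root = np.random.SeedSequence(seed)
    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    for child in root.spawn(restarts):
        rng = np.random.default_rng(child)
        w, c, obj = _mu_factorize(values, k, max_iter, tol, rng, check_monotone)
        if best is None or obj < best[2]:
            best = (w, c, obj)
    w, c, obj = best
    recon = w @ c
    return SynergySet(
        W=w, C=c, k=k,
        vaf_global=_vaf_pct(values, recon),
        vaf_muscle=_vaf_rows(values, recon),
        residual=values - recon,
        restarts_used=restarts,
        seed=seed,
        objective=obj,
    )


def vaf_global(m: EnvelopeMatrix | np.ndarray, s: SynergySet) -> float:
    """Uncentered global VAF in percent: 100 (1 - ||M-WC||^2 / ||M||^2)."""
    values = m.values if isinstance(m, EnvelopeMatrix) else np.asarray(m, dtype=float)
    return _vaf_pct(values, s.W @ s.C)


def vaf_muscle(m: EnvelopeMatrix | np.ndarray, s: SynergySet) -> np.ndarray:
    """Uncentered per-muscle VAF, one percent value per row of M."""
    values = m.values if isinstance(m, EnvelopeMatrix) else np.asarray(m, dtype=float)
    recon = s.W @ s.C
    return np.array([_vaf_pct(values[i:i + 1], recon[i:i + 1])
                     for i in range(values.shape[0])])


def select_dimensionality(m: EnvelopeMatrix | np.ndarray, k_max: int = 8,
                          vaf_global_pct: float = 90.0,
                          vaf_muscle_pct: float = 75.0,
                          vaf_gain_pct: float = 5.0,
                          restarts: int = 20, max_iter: int = 2000,
                          tol: float = 1e-6, seed: int = 0) -> SynergySet:
    """Smallest K meeting the three VAF criteria.

    (a) global VAF > ``vaf_global_pct``; (b) every muscle's VAF >
    ``vaf_muscle_pct``; (c) going to K+1 gains <= ``vaf_gain_pct``
    percentage points of mean per-muscle VAF (vacuous at K = k_max).
    All candidate factorizations are cached in ``diagnostics['by_k']``.
    """
    values = m.values if isinstance(m, EnvelopeMatrix) else np.asarray(m, dtype=float)
    k_cap = min(k_max, *values.shape)
    by_k: dict[int, SynergySet] = {}

    def fact(k: int) -> SynergySet:
        if k not in by_k:
            by_k[k] = nnmf(values, k, restarts=restarts, max_iter=max_iter,
                           tol=tol, seed=seed + k)
        return by_k[k]

    chosen: Optional[SynergySet] = None
    for k in range(1, k_cap + 1):
        s = fact(k)
        if s.vaf_global <= vaf_global_pct or np.any(s.vaf_muscle <= vaf_muscle_pct):
            continue
        if k < k_cap:
            gain = float(np.mean(fact(k + 1).vaf_muscle) - np.mean(s.vaf_muscle))
            if gain > vaf_gain_pct:
                continue
        chosen = s
        break

    curve = {k: {"vaf_global": by_k[k].vaf_global,
                 "vaf_muscle": by_k[k].vaf_muscle.tolist()}
             for k in sorted(by_k)}
    if chosen is None:
        raise DimensionalityError(
            f"no K <= {k_cap} satisfies the VAF criteria "
            f"(>{vaf_global_pct}% global, >{vaf_muscle_pct}% per muscle)",
            vaf_curve=curve,
        )
    chosen.diagnostics["vaf_curve"] = curve
    chosen.diagnostics["by_k"] = by_k
    return chosen


def unscale_and_normalize(s: SynergySet, unit_var_scales: np.ndarray) -> SynergySet:
    """Undo unit-variance scaling and unit-max-normalize synergy vectors.

    Row i of W is multiplied by the stored per-muscle scale, returning the
    synergies to physiological scale; each column of W is then rescaled to
    unit maximum with the reciprocal folded into the matching row of C, so
    the reconstruction W C is unchanged.
    """
    scales = np.asarray(unit_var_scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("unit-variance scales must be positive")
    if scales.shape != (s.W.shape[0],):
        raise ValueError("one scale per muscle required")
    w = s.W * scales[:, None]
    col_max = w.max(axis=0)
    if np.any(col_max <= 0):
        raise ValueError("synergy vector with zero maximum cannot be normalized")
    w_n = w / col_max
    c_n = s.C * col_max[:, None]
    return SynergySet(
        W=w_n, C=c_n, k=s.k,
        vaf_global=s.vaf_global, vaf_muscle=s.vaf_muscle,
        residual=s.residual, restarts_used=s.restarts_used,
        seed=s.seed, objective=s.objective, diagnostics=dict(s.diagnostics),
    )
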