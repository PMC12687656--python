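"""Planted-truth recovery checks for synthetic cohorts.

Because no public dataset accompanies the protocol, the package validates
itself against its own generative model: run the full pipeline on a
synthetic cohort and measure how well the known ground truth is recovered —
selected synergy dimensionality, synergy-vector shape (cosine similarity),
cluster count, cross-stage matching, scripted kinematic events, and the
power / type-I behaviour of the paired comparisons. These functions are
used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import clustering, kinematics, stats
from .pipeline import StageReport
from .synthetic import CohortTruth

__all__ = [
    "dimensionality_recovery",
    "synergy_cosine_recovery",
    "cluster_sensitivity",
    "event_recovery",
    "weight_reduction_power",
    "paired_shift_power",
    "null_weight_rejection_rate",
]


def dimensionality_recovery(report: StageReport, k_true: int = 5) -> float:
    """Percent of participant-stage extractions that selected ``k_true``."""
    dims = report.dimensionality_table
    values = np.concatenate([dims["early"].to_numpy(), dims["late"].to_numpy()])
    return 100.0 * float(np.mean(values == k_true))


def _greedy_cosines(w_hat: np.ndarray, w_ref: np.ndarray) -> list[float]:
    a = w_hat / np.linalg.norm(w_hat, axis=0)
    b = w_ref / np.linalg.norm(w_ref, axis=0)
    sim = b.T @ a
    out = []
    for _ in range(min(sim.shape)):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        out.append(float(sim[i, j]))
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
    return out


def synergy_cosine_recovery(report: StageReport, truth: CohortTruth) -> float:
    """Mean greedy-matched cosine between recovered and planted synergies."""
    cosines = []
    for stage in ("early", "late"):
        for pid, ps in report.extractions[stage].items():
            cosines.extend(_greedy_cosines(ps.synergies.W,
                                           truth.participant_w[pid][stage]))
    return float(np.mean(cosines))


def cluster_sensitivity(report: StageReport, stage: str = "late",
                        extra_k: int = 6, seed: int = 0) -> list[float]:
    """Match r of each base-solution centroid to the ``extra_k`` rerun.

    Mirrors the 5-vs-6-cluster sensitivity analysis: recluster the stage's
    pooled synergies with one more cluster and report, per original mode,
    the Pearson r to its best available rerun centroid.
    """
    base = report.modes[stage]
    pooled = clustering.PooledSynergies(stage=stage, vectors=base.vectors,
                                        labels=base.labels)
    rerun = clustering.cluster_stage(pooled, k=extra_k, seed=seed)
    match = clustering.match_stages(base, rerun, threshold=0.99)
    return [r for _, _, r in match.pairs]


def event_recovery(sessions, truth: CohortTruth, n_participants: int = 8,
                   n_trials: int = 3) -> dict:
    """Scripted-vs-detected event and step-length errors on a cohort subset."""
    frame_errs, len_errs_mm = [], []
    for session in sessions[:n_participants]:
        scripts = truth.scripts[session.participant_id]
        for bundle, script in zip(session.trials[:n_trials], scripts[:n_trials]):
            ev = kinematics.detect_events(bundle.markers, bundle.recovery_side)
            rate = bundle.markers.rate_hz
            frame_errs.extend([
                (ev.bon_s - script.bon_s) * rate,
                (ev.liftoff_s - script.liftoff_s) * rate,
                (ev.td_s - script.td_s) * rate,
            ])
            filtered = kinematics.lowpass_markers(bundle.markers, 6.0)
            _, _, length, _ = kinematics.step_metrics(filtered, ev)
            len_errs_mm.append((length - script.step_length_m) * 1000.0)
    return {
        "max_abs_event_err_frames": float(np.max(np.abs(frame_errs))),
        "step_length_mae_mm": float(np.mean(np.abs(len_errs_mm))),
        "n_trials": len(len_errs_mm),
    }


def weight_reduction_power(delta: float = 0.2, delta_sd: float = 0.1,
                           n: int = 26, n_cohorts: int = 100,
                           weight_sd: float = 0.05, seed: int = 0) -> float:
    """Power of the per-muscle paired t to detect a planted weight drop.

    Per participant the early and late weight share a baseline and
    independent measurement jitter (``weight_sd``, matching the generator's
    per-participant synergy jitter); the late weight additionally drops by
    N(delta, delta_sd).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        base = rng.uniform(0.3, 0.7, n)
        early = base + rng.normal(0, weight_sd, n)
        late = base + rng.normal(0, weight_sd, n) - rng.normal(delta, delta_sd, n)
        r = stats.paired_t(early, late)
        if r.p < 0.05 and r.statistic > 0:
            hits += 1
    return hits / n_cohorts


def paired_shift_power(shift: float, trial_sd: float, n: int = 26,
                       n_cohorts: int = 100, n_trials_per_stage: int = 2,
                       seed: int = 0) -> float:
    """Power of the stage-mean paired t for a planted per-trial shift.

    Emulates the kinematic comparison: each stage value is the mean of two
    trials with trial-to-trial jitter ``trial_sd``; the late stage is
    shifted by ``shift``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        early = rng.normal(0.0, trial_sd, (n, n_trials_per_stage)).mean(axis=1)
        late = shift + rng.normal(0.0, trial_sd, (n, n_trials_per_stage)).mean(axis=1)
        r = stats.paired_t(early, late)
        if r.p < 0.05 and np.sign(r.statistic) == -np.sign(shift):
            hits += 1
    return hits / n_cohorts


def null_weight_rejection_rate(n: int = 26, n_tests: int = 4000,
                               weight_sd: float = 0.05, seed: int = 0) -> float:
    """Type-I rate of the per-muscle paired t with no planted change."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_tests):
        base = rng.uniform(0.3, 0.7, n)
        early = base + rng.normal(0, weight_sd, n)
        late = base + rng.normal(0, weight_sd, n)
        if stats.paired_t(early, late).p < 0.05:
            rejections += 1
    return rejections / n_tests
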