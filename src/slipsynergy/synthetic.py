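"""Seeded synthetic stance-slip sessions with known ground truth.

The study's raw trials are not deposited, so this module generates complete
sessions — EMG, markers, belt and load-cell traces — from a known generative
model so every pipeline stage can be tested end-to-end:

* EMG: the linear envelope is a non-negative mixture of planted synergy
  vectors driven by Gaussian-bump activation curves plus truncated-Gaussian
  envelope noise; the raw signal is that envelope multiplied by a broadband
  unit-variance carrier (white noise band-passed 35-250 Hz), so the
  high-pass/rectify/low-pass chain genuinely has work to do and recovers
  the envelope up to a scale factor.
* Belt: a three-phase trapezoidal velocity profile (accelerate at a to the
  plateau v, coast, decelerate at -a) whose integral equals the commanded
  displacement. Training profile 0.18 m / 0.45 m/s / 11.35 m/s^2;
  familiarization 0.14 m / 0.36 m/s / 9 m/s^2.
* Markers: a standing posture scaled to body height; the recovery heel and
  toe execute a minimum-jerk backward step of scripted length between the
  scripted liftoff and touchdown; the belt marker follows the belt
  position trace from the scripted onset; 1 mm additive Gaussian noise.
* Load cell: low baseline tension with a smooth pulse during the step whose
  peak is a scripted fraction of body weight.

Cohorts emulate the study design: 26 participants, 10 slip trials, stages
S1-S2 (early) vs S9-S10 (late), per-participant jitter of the synergy
weights, and optional planted late-stage changes (synergy reweighting,
shorter step initiation, longer steps) whose recovery the tests check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .io_model import (
    CANONICAL_CHANNELS,
    CANONICAL_LABELS,
    EmgTrial,
    LoadCellTrial,
    MarkerTrial,
    Session,
    TrialBundle,
)

__all__ = [
    "BeltProfile",
    "BumpParams",
    "TrialScript",
    "ReweightEntry",
    "GroundTruth",
    "make_belt_profile",
    "make_ground_truth",
    "activation_curves",
    "synthesize_emg",
    "synthesize_markers",
    "synthesize_loadcell",
    "make_session",
    "make_cohort",
    "TRAINING_BELT",
    "FAMILIARIZATION_BELT",
]

#: (displacement m, peak velocity m/s, acceleration m/s^2) of the two protocols
TRAINING_BELT = (0.18, 0.45, 11.35)
FAMILIARIZATION_BELT = (0.14, 0.36, 9.0)


# ---------------------------------------------------------------------------
# Belt profile

@dataclass
class BeltProfile:
    displacement_m: float
    peak_velocity_mps: float
    accel_mps2: float
    t_acc: float
    t_const: float
    t_dec: float
    rate_hz: float
    velocity: np.ndarray            # sampled from motion start
    position: np.ndarray

    @property
    def duration_s(self) -> float:
        return self.t_acc + self.t_const + self.t_dec


def make_belt_profile(displacement_m: float, velocity_mps: float,
                      accel_mps2: float, rate_hz: float = 120.0) -> BeltProfile:
    """Three-phase trapezoidal belt velocity profile.

    Phase durations: t_acc = t_dec = v/a, t_const = (d - v^2/a)/v. The
    sampled velocity trace integrates to the commanded displacement within
    1e-3 m.
    """
    if displacement_m <= velocity_mps ** 2 / accel_mps2:
        raise ValueError(
            "infeasible trapezoid: displacement <= v^2/a; use a triangular profile"
        )
    t_acc = velocity_mps / accel_mps2
    t_const = (displacement_m - velocity_mps ** 2 / accel_mps2) / velocity_mps
    t_dec = t_acc
    duration = t_acc + t_const + t_dec
    # dense integration grid, then resample to rate_hz
    t = np.arange(0.0, duration + 0.5 / rate_hz, 1.0 / rate_hz)
    v = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti < t_acc:
            v[i] = accel_mps2 * ti
        elif ti < t_acc + t_const:
            v[i] = velocity_mps
        elif ti <= duration:
            v[i] = max(0.0, velocity_mps - accel_mps2 * (ti - t_acc - t_const))
        else:
            v[i] = 0.0
    # closed-form position avoids sampled-integration error
    pos = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti < t_acc:
            pos[i] = 0.5 * accel_mps2 * ti ** 2
        elif ti < t_acc + t_const:
            pos[i] = 0.5 * velocity_mps * t_acc + velocity_mps * (ti - t_acc)
        else:
            tau = min(ti, duration) - t_acc - t_const
            pos[i] = (0.5 * velocity_mps * t_acc + velocity_mps * t_const
                      + velocity_mps * tau - 0.5 * accel_mps2 * tau ** 2)
    return BeltProfile(displacement_m, velocity_mps, accel_mps2,
                       t_acc, t_const, t_dec, rate_hz, v, pos)


# ---------------------------------------------------------------------------
# Ground truth

@dataclass
class BumpParams:
    peak_time_pct: float
    width_pct: float
    amplitude: float


@dataclass
class TrialScript:
    trial_id: str
    bon_s: float
    liftoff_s: float
    td_s: float
    step_length_m: float
    duration_s: float = 8.0
    recovery_side: str = "right"
    fall_peak_bw_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.bon_s < self.liftoff_s < self.td_s < self.duration_s):
            raise ValueError("scripted events must be ordered within the trial")


@dataclass
class ReweightEntry:
    mode: int
    muscle: int                     # canonical channel index
    delta_mean: float               # additive late-stage weight change
    delta_sd: float = 0.1           # across participants


@dataclass
class GroundTruth:
    W_true: np.ndarray              # [8 x K], unit-max columns
    bumps: list[BumpParams]
    noise_frac: float               # envelope noise sd / mean envelope
    reweight: list[ReweightEntry]
    seed: int
    template: str = "fig4_like"

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        if np.any(self.W_true < 0):
            raise ValueError("planted synergy weights must be non-negative")
        cos = _pairwise_cosine(self.W_true)
        if np.any(cos >= 0.95):
            raise ValueError("planted synergy columns must have pairwise cosine < 0.95")

    @property
    def k(self) -> int:
        return self.W_true.shape[1]

    def to_json(self) -> str:
        d = {
            "template": self.template,
            "seed": self.seed,
            "noise_frac": self.noise_frac,
            "W_true": self.W_true.tolist(),
            "muscle_order": list(CANONICAL_LABELS),
            "bumps": [asdict(b) for b in self.bumps],
            "reweight": [asdict(r) for r in self.reweight],
        }
        return json.dumps(d, indent=2)


def _pairwise_cosine(w: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(w, axis=0)
    g = (w.T @ w) / np.outer(norms, norms)
    return g[np.triu_indices_from(g, k=1)]


#: Dominant canonical channel per mode in the five-mode template, in
#: activation-peak order: W_TA (both sides), W_S_VLAT, W_R_GAS, W_R_VLAT,
#: W_S_GAS.
_FIG4_DOMINANTS = (
    ("R_TA", "S_TA"),
    ("S_VLAT",),
    ("R_GAS",),
    ("R_VLAT",),
    ("S_GAS",),
)


def make_ground_truth(k: int = 5, template: str = "fig4_like", seed: int = 0,
                      noise_frac: float = 0.10,
                      reweight: Sequence[ReweightEntry] = ()) -> GroundTruth:
    """Planted synergy vectors and activation-bump parameters.

    ``fig4_like`` places weight ~1 on each mode's dominant muscle(s) with
    sub-dominant weights below 0.6 and activation peaks ordered in time;
    ``random`` draws unit-max columns uniformly, enforcing pairwise cosine
    < 0.95 by rejection.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if template == "fig4_like":
        if k != 5:
            raise ValueError("fig4_like template defines exactly 5 modes")
        for _ in range(1000):
            # sparse, low sub-dominant weights in [0, 0.6]: most muscles
            # contribute little to modes they do not dominate
            w = 0.6 * rng.beta(1.0, 8.0, size=(8, k))
            for j, doms in enumerate(_FIG4_DOMINANTS):
                for d_i, lab in enumerate(doms):
                    idx = CANONICAL_LABELS.index(lab)
                    w[idx, j] = 1.0 if d_i == 0 else rng.uniform(0.96, 0.99)
            # posterior-chain co-activation: recovery BFLH assists the
            # recovery-GAS mode with a strong but sub-dominant weight (the
            # natural site for planted reweighting, since unit-max
            # normalization would absorb changes to a dominant muscle)
            w[CANONICAL_LABELS.index("R_BFLH"), 2] = rng.uniform(0.45, 0.60)
            if np.all(_pairwise_cosine(w) < 0.95):
                break
        else:
            raise RuntimeError("could not satisfy synergy distinctness in 1000 draws")
        peaks = np.array([18.0, 34.0, 50.0, 66.0, 82.0])
    elif template == "random":
        for _ in range(1000):
            w = rng.uniform(0.0, 1.0, size=(8, k))
            w = w / w.max(axis=0)
            if np.all(_pairwise_cosine(w) < 0.95):
                break
        else:
            raise RuntimeError("could not satisfy synergy distinctness in 1000 draws")
        peaks = np.sort(rng.uniform(10, 90, size=k))
    else:
        raise ValueError(f"unknown template {template!r}")

    bumps = [BumpParams(peak_time_pct=float(p),
                        width_pct=float(rng.uniform(5.5, 7.5)),
                        amplitude=float(rng.uniform(0.8, 1.2)))
             for p in peaks]
    return GroundTruth(W_true=w, bumps=bumps, noise_frac=noise_frac,
                       reweight=list(reweight), seed=seed, template=template)


# ---------------------------------------------------------------------------
# EMG synthesis

def activation_curves(bumps: Sequence[BumpParams], pct: np.ndarray,
                      amp_jitter: Optional[np.ndarray] = None) -> np.ndarray:
    """Gaussian-bump activations [K x len(pct)] on a percent-of-window axis."""
    k = len(bumps)
    amps = np.ones(k) if amp_jitter is None else amp_jitter
    c = np.empty((k, pct.size))
    for i, b in enumerate(bumps):
        c[i] = amps[i] * b.amplitude * np.exp(
            -0.5 * ((pct - b.peak_time_pct) / b.width_pct) ** 2
        )
    return c


def _broadband_carrier(n: int, rate_hz: float, rng: np.random.Generator,
                       band: tuple[float, float] = (35.0, 250.0)) -> np.ndarray:
    x = rng.standard_normal(n)
    nyq = rate_hz / 2.0
    sos = sps.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, x)
    return x / x.std()


_BASELINE = 0.02  # resting envelope level, fraction of bump amplitude scale


def synthesize_emg(gt: GroundTruth, script: TrialScript, w: Optional[np.ndarray] = None,
                   rate_hz: float = 600.0, seed: int = 0,
                   pre_ms: float = 100.0, post_ms: float = 100.0,
                   max_bursts: bool = False, with_truth: bool = False):
    """One trial's raw EMG: planted envelope times a broadband carrier.

    The activation bumps live on the BON-pre .. TD+post window (percent
    axis); outside it only a small resting envelope remains. ``w`` overrides
    the planted synergy matrix (per-participant jitter, reweighting).
    With ``with_truth`` the noise-free planted envelope [8 x n_samples] is
    returned alongside the trial.

    ``max_bursts`` adds one maximal co-contraction burst per muscle at a
    random time in the window, with a common amplitude above every
    synergy-driven level. Real sessions contain such non-synergy activity
    (startle responses, variable co-contraction in the transition trials),
    and it is what anchors each muscle's session-wide normalization maximum;
    without it, per-muscle max-normalization would inflate every muscle's
    strongest synergy weight to 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w = gt.W_true if w is None else np.asarray(w, dtype=float)
    n = int(round(script.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    t0 = script.bon_s - pre_ms / 1000.0
    t1 = script.td_s + post_ms / 1000.0
    pct = (t - t0) / (t1 - t0) * 100.0
    amp_jitter = rng.uniform(0.9, 1.1, size=gt.k)
    c = activation_curves(gt.bumps, pct, amp_jitter)
    c[:, (pct < -5) | (pct > 105)] = 0.0
    env = w @ c + _BASELINE
    if max_bursts:
        # common ceiling amplitude, clear of the strongest synergy envelope
        ceiling = 1.25 * float((w @ c).max())
        for m in range(8):
            center = rng.uniform(5.0, 95.0)
            env[m] += ceiling * np.exp(-0.5 * ((pct - center) / 6.0) ** 2)
    clean_env = env.copy()
    if gt.noise_frac > 0:
        in_window = (pct >= 0) & (pct <= 100)
        mean_level = env[:, in_window].mean()
        noise = rng.normal(0.0, gt.noise_frac * mean_level, size=env.shape)
        env = np.clip(env + noise, 0.0, None)
    carrier = np.vstack([_broadband_carrier(n, rate_hz, rng) for _ in range(8)])
    trial = EmgTrial(trial_id=script.trial_id, stage="other",
                     channels=CANONICAL_CHANNELS, signal=env * carrier,
                     rate_hz=rate_hz)
    if with_truth:
        return trial, clean_env
    return trial


# ---------------------------------------------------------------------------
# Marker synthesis

def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile, 0 -> 1 over tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _standing_posture(height_m: float) -> dict[str, np.ndarray]:
    """Marker positions (AP, ML, vertical) of a static standing posture."""
    h = height_m
    return {
        "head": np.array([0.00, 0.00, 0.93 * h]),
        "L_shoulder": np.array([0.00, -0.18 * h / 1.7, 0.82 * h]),
        "R_shoulder": np.array([0.00, 0.18 * h / 1.7, 0.82 * h]),
        "L_elbow": np.array([0.00, -0.18 * h / 1.7, 0.63 * h]),
        "R_elbow": np.array([0.00, 0.18 * h / 1.7, 0.63 * h]),
        "L_wrist": np.array([0.00, -0.18 * h / 1.7, 0.48 * h]),
        "R_wrist": np.array([0.00, 0.18 * h / 1.7, 0.48 * h]),
        "L_hip": np.array([0.00, -0.09 * h / 1.7, 0.53 * h]),
        "R_hip": np.array([0.00, 0.09 * h / 1.7, 0.53 * h]),
        "L_knee": np.array([0.00, -0.10 * h / 1.7, 0.28 * h]),
        "R_knee": np.array([0.00, 0.10 * h / 1.7, 0.28 * h]),
        "L_ankle": np.array([-0.02, -0.10 * h / 1.7, 0.05 * h]),
        "R_ankle": np.array([-0.02, 0.10 * h / 1.7, 0.05 * h]),
        "L_heel": np.array([-0.05, -0.10 * h / 1.7, 0.02]),
        "R_heel": np.array([-0.05, 0.10 * h / 1.7, 0.02]),
        "L_toe": np.array([0.15, -0.11 * h / 1.7, 0.02]),
        "R_toe": np.array([0.15, 0.11 * h / 1.7, 0.02]),
        "belt": np.array([0.30, 0.00, 0.01]),
    }


def synthesize_markers(script: TrialScript, height_m: float, belt: BeltProfile,
                       rate_hz: float = 120.0, seed: int = 0,
                       noise_sd_m: float = 0.001) -> MarkerTrial:
    """Scripted marker trajectories for one trial.

    The belt marker follows the belt position trace from the scripted BON;
    the recovery-side heel, toe and ankle translate backward by the scripted
    step length along a minimum-jerk profile between liftoff and TD. All
    other markers hold the standing posture. Gaussian noise (default 1 mm)
    is added to every coordinate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(script.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    posture = _standing_posture(height_m)
    names = list(posture)
    pos = np.empty((len(names), n, 3))
    for i, name in enumerate(names):
        pos[i] = posture[name]

    # belt translation (AP) from scripted BON
    belt_disp = np.interp(t - script.bon_s,
                          np.arange(belt.position.size) / belt.rate_hz,
                          belt.position, left=0.0, right=belt.position[-1])
    pos[names.index("belt"), :, 0] += belt_disp

    # recovery-foot backward step with a small vertical lift
    rec = script.recovery_side[0].upper()
    tau = (t - script.liftoff_s) / (script.td_s - script.liftoff_s)
    step_ap = -script.step_length_m * _min_jerk(tau)
    lift_z = 0.04 * np.sin(np.pi * np.clip(tau, 0.0, 1.0))
    for marker in (f"{rec}_heel", f"{rec}_toe", f"{rec}_ankle"):
        i = names.index(marker)
        pos[i, :, 0] += step_ap
        pos[i, :, 2] += lift_z

    if noise_sd_m > 0:
        pos += rng.normal(0.0, noise_sd_m, size=pos.shape)
    return MarkerTrial(names, pos, rate_hz)


def synthesize_loadcell(script: TrialScript, body_weight_n: float,
                        rate_hz: float = 600.0, seed: int = 0) -> LoadCellTrial:
    """Baseline harness tension plus a smooth pulse peaking at the scripted
    fraction of body weight shortly after liftoff."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(script.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    base = 5.0 + np.abs(rng.normal(0.0, 1.0, size=n))
    center = 0.5 * (script.liftoff_s + script.td_s)
    width = max(0.1, 0.5 * (script.td_s - script.liftoff_s))
    pulse = script.fall_peak_bw_frac * body_weight_n * np.exp(
        -0.5 * ((t - center) / width) ** 2
    )
    force = np.clip(base + pulse, 0.0, None)
    return LoadCellTrial(force=force, rate_hz=rate_hz, body_weight_n=body_weight_n)


# ---------------------------------------------------------------------------
# Sessions and cohorts

@dataclass
class CohortTruth:
    """Per-cohort ground truth: planted model plus per-participant scripts."""

    gt: GroundTruth
    participant_w: dict[str, dict[str, np.ndarray]]   # pid -> stage -> [8 x K]
    scripts: dict[str, list[TrialScript]]             # pid -> 10 trial scripts


def _participant_scripts(pid: str, rng: np.random.Generator,
                         initiation_shift_s: float = -0.03,
                         step_length_shift_m: float = 0.03,
                         n_trials: int = 10) -> list[TrialScript]:
    """Scripted events for one participant's trials.

    Early baseline: initiation 0.25 s, execution 0.18 s, step length 0.17 m;
    late-stage trials apply the planted shifts (shorter initiation, longer
    step). Trial-to-trial jitter: 0.02 s on initiation, 0.015 m on length.
    """
    base_init = rng.normal(0.25, 0.02)
    base_len = rng.normal(0.17, 0.02)
    scripts = []
    for i in range(n_trials):
        late = i >= n_trials - 2
        init = base_init + (initiation_shift_s if late else 0.0) + rng.normal(0, 0.02)
        length = base_len + (step_length_shift_m if late else 0.0) + rng.normal(0, 0.015)
        init = max(0.12, init)
        length = max(0.08, length)
        execu = max(0.12, rng.normal(0.18, 0.015))
        bon = rng.uniform(2.0, 4.0)
        scripts.append(TrialScript(
            trial_id=f"S{i + 1}",
            bon_s=bon,
            liftoff_s=bon + init,
            td_s=bon + init + execu,
            step_length_m=length,
        ))
    return scripts


def make_session(gt: GroundTruth, pid: str, seed: int,
                 height_m: float = 1.70, weight_kg: float = 70.0,
                 initiation_shift_s: float = -0.03,
                 step_length_shift_m: float = 0.03,
                 weight_jitter_sd: float = 0.05,
                 emg_rate_hz: float = 600.0, marker_rate_hz: float = 120.0
                 ) -> tuple[Session, dict[str, np.ndarray], list[TrialScript]]:
    """One participant's full 10-trial session with per-participant truth."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    scripts = _participant_scripts(pid, rng, initiation_shift_s, step_length_shift_m)

    w_early = np.clip(gt.W_true + rng.normal(0, weight_jitter_sd, gt.W_true.shape),
                      0.0, None)
    w_early /= w_early.max(axis=0)
    w_late = w_early.copy()
    for entry in gt.reweight:
        delta = rng.normal(entry.delta_mean, entry.delta_sd)
        w_late[entry.muscle, entry.mode] = max(
            0.0, w_late[entry.muscle, entry.mode] + delta
        )
    w_late = w_late / w_late.max(axis=0)

    belt = make_belt_profile(*TRAINING_BELT, rate_hz=marker_rate_hz)
    body_weight_n = weight_kg * 9.81
    bundles = []
    trial_seeds = ss.spawn(len(scripts))
    for i, (script, tss) in enumerate(zip(scripts, trial_seeds)):
        sub = tss.generate_state(3)
        w = w_late if i >= len(scripts) - 2 else w_early
        # transition trials (S3-S8) carry the maximal co-contraction bursts
        # that anchor each muscle's session-wide normalization maximum
        mid = 2 <= i < len(scripts) - 2
        emg = synthesize_emg(gt, script, w=w, rate_hz=emg_rate_hz,
                             seed=int(sub[0] % (2 ** 31)), max_bursts=mid)
        markers = synthesize_markers(script, height_m, belt,
                                     rate_hz=marker_rate_hz,
                                     seed=int(sub[1] % (2 ** 31)))
        loadcell = synthesize_loadcell(script, body_weight_n,
                                       rate_hz=emg_rate_hz,
                                       seed=int(sub[2] % (2 ** 31)))
        bundles.append(TrialBundle(
            trial_id=script.trial_id, stage="other", emg=emg,
            markers=markers, loadcell=loadcell,
            recovery_side=script.recovery_side,
        ))
    session = Session(participant_id=pid, trials=bundles,
                      body_height_m=height_m, body_weight_kg=weight_kg)
    return session, {"early": w_early, "late": w_late}, scripts


def make_cohort(n: int = 26, template: str = "fig4_like", k: int = 5,
                noise_frac: float = 0.10,
                reweight: Sequence[ReweightEntry] = (),
                initiation_shift_s: float = -0.03,
                step_length_shift_m: float = 0.03,
                seed: int = 0) -> tuple[list[Session], CohortTruth]:
    """A full study-structured cohort with planted ground truth.

    Defaults mirror the study conditions: 26 participants, five planted
    modes, 10% envelope noise, and (when requested) late-stage reweighting
    plus the kinematic training shifts.
    """
    if n < 3:
        raise ValueError("cohort needs at least 3 participants")
    ss = np.random.SeedSequence(seed)
    gt = make_ground_truth(k=k, template=template, seed=seed,
                           noise_frac=noise_frac, reweight=reweight)
    sessions, pw, scripts = [], {}, {}
    rng = np.random.default_rng(ss)
    for i, child in enumerate(ss.spawn(n)):
        pid = f"P{i + 1:02d}"
        height = float(np.clip(rng.normal(1.70, 0.08), 1.5, 1.95))
        weight = float(np.clip(rng.normal(70.0, 10.0), 45, 110))
        session, w_by_stage, sc = make_session(
            gt, pid, seed=int(child.generate_state(1)[0] % (2 ** 31)),
            height_m=height, weight_kg=weight,
            initiation_shift_s=initiation_shift_s,
            step_length_shift_m=step_length_shift_m,
        )
        sessions.append(session)
        pw[pid] = w_by_stage
        scripts[pid] = sc
    return sessions, CohortTruth(gt=gt, participant_w=pw, scripts=scripts)
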