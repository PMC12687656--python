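"""Reactive-balance kinematics of a stance slip trial.

Events on the common clock: belt onset (BON, belt-marker AP velocity first
exceeding 0.05 m/s, sustained), recovery-foot liftoff and touchdown (TD)
from the heel marker's AP velocity. Outcomes mirror the standard reactive
stepping battery: step initiation/execution times, step length/width at TD,
whole-body COM position (normalized to the base of support) and velocity
(relative to the recovery heel in AP), trunk inclination and arm flexion at
TD, and the harness-load fall classification (peak force > 30% body
weight).

The COM comes from a table-driven segmental model: each segment is a pair
of proximal/distal markers with a mass fraction and a COM location fraction
along the segment. A 13-segment default table (Dempster-style fractions) is
bundled and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_model import LoadCellTrial, MarkerTrial, TrialBundle
from .preprocess import _zero_phase_butter

__all__ = [
    "TrialEvents",
    "KinematicOutcomes",
    "SegmentRow",
    "DEFAULT_SEGMENT_TABLE",
    "lowpass_markers",
    "detect_bon",
    "detect_step_events",
    "detect_events",
    "step_metrics",
    "com_estimate",
    "com_state",
    "trunk_arm_angles",
    "detect_fall",
    "compute_outcomes",
]

AP, ML, VERT = 0, 1, 2


@dataclass
class TrialEvents:
    bon_s: float
    liftoff_s: float
    td_s: float
    recovery_side: str = "right"    # "left" or "right"

    def __post_init__(self) -> None:
        if not (self.bon_s < self.liftoff_s < self.td_s):
            raise ValueError(
                f"events out of order: BON {self.bon_s}, liftoff {self.liftoff_s}, "
                f"TD {self.td_s}"
            )


@dataclass
class KinematicOutcomes:
    step_initiation_s: float
    step_execution_s: float
    step_length_m: float
    step_width_m: float
    ap_com_pos_norm: float          # fraction of BOS length
    ml_com_pos_norm: float          # fraction of BOS width
    ap_com_vel_mps: float           # COM minus recovery-heel AP velocity at TD
    ml_com_vel_mps: float           # absolute ML velocity at TD
    trunk_angle_deg: float          # < 90 flexion, > 90 extension
    arm_flexion_deg: float
    fall: bool


@dataclass(frozen=True)
class SegmentRow:
    name: str
    proximal: str
    distal: str
    mass_fraction: float
    com_fraction: float             # COM location along proximal -> distal


#: 13-segment whole-body model on the package's marker set. Mass fractions
#: follow classic cadaver-study proportions (head 8.1%, trunk+pelvis 49.7%
#: split per side, thigh 10%, shank 4.65%, foot 1.45%, upper arm 2.8%,
#: forearm+hand 2.2%); fractions sum to 1.
DEFAULT_SEGMENT_TABLE: tuple[SegmentRow, ...] = (
    SegmentRow("head", "head", "head", 0.081, 0.0),
    SegmentRow("trunk_L", "L_shoulder", "L_hip", 0.2485, 0.5),
    SegmentRow("trunk_R", "R_shoulder", "R_hip", 0.2485, 0.5),
    SegmentRow("thigh_L", "L_hip", "L_knee", 0.100, 0.433),
    SegmentRow("thigh_R", "R_hip", "R_knee", 0.100, 0.433),
    SegmentRow("shank_L", "L_knee", "L_ankle", 0.0465, 0.433),
    SegmentRow("shank_R", "R_knee", "R_ankle", 0.0465, 0.433),
    SegmentRow("foot_L", "L_heel", "L_toe", 0.0145, 0.5),
    SegmentRow("foot_R", "R_heel", "R_toe", 0.0145, 0.5),
    SegmentRow("upperarm_L", "L_shoulder", "L_elbow", 0.028, 0.436),
    SegmentRow("upperarm_R", "R_shoulder", "R_elbow", 0.028, 0.436),
    SegmentRow("forearm_L", "L_elbow", "L_wrist", 0.022, 0.5),
    SegmentRow("forearm_R", "R_elbow", "R_wrist", 0.022, 0.5),
)


def lowpass_markers(m: MarkerTrial, cutoff_hz: float = 6.0) -> MarkerTrial:
    """Zero-phase low-pass of every marker coordinate (effective 4th order)."""
    filtered = _zero_phase_butter(
        np.moveaxis(m.positions, 1, -1), cutoff_hz, m.rate_hz, "lowpass"
    )
    return MarkerTrial(list(m.marker_names), np.moveaxis(filtered, -1, 1),
                       m.rate_hz, dict(m.gap_report))


def _central_velocity(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Central-difference velocity, one-sided at the ends."""
    return np.gradient(x, 1.0 / rate_hz, axis=-1 if x.ndim == 1 else 0)


def _first_sustained(mask: np.ndarray, sustain: int, start: int = 0) -> Optional[int]:
    """First index >= start opening a run of at least ``sustain`` True frames."""
    n = len(mask)
    run = 0
    for i in range(start, n):
        run = run + 1 if mask[i] else 0
        if run >= sustain:
            return i - sustain + 1
    return None


def _cross_up(v: np.ndarray, idx: int, thresh: float, rate_hz: float) -> float:
    """Sub-frame time of the upward threshold crossing ending at frame idx."""
    if idx == 0 or v[idx - 1] >= thresh:
        return idx / rate_hz
    frac = (thresh - v[idx - 1]) / (v[idx] - v[idx - 1])
    return (idx - 1 + frac) / rate_hz


def _cross_down(v: np.ndarray, idx: int, thresh: float, rate_hz: float) -> float:
    """Sub-frame time of the downward threshold crossing ending at frame idx."""
    if idx == 0 or v[idx - 1] <= thresh:
        return idx / rate_hz
    frac = (v[idx - 1] - thresh) / (v[idx - 1] - v[idx])
    return (idx - 1 + frac) / rate_hz


def detect_bon(belt: np.ndarray, rate_hz: float, v_thresh: float = 0.05,
               sustain: int = 3, settle_s: float = 0.5) -> float:
    """Belt onset: first sustained AP-velocity threshold crossing.

    ``belt`` is the [n_frames x 3] belt-marker trajectory. The crossing must
    hold for ``sustain`` consecutive frames so single-frame noise spikes are
    ignored; the reported time is the sub-frame interpolated crossing. The
    first ``settle_s`` seconds are excluded from the search: zero-phase
    filtering leaves an edge transient there, and the protocol triggers the
    belt no earlier than 2 s into the trial.
    """
    v = _central_velocity(belt[:, AP], rate_hz)
    idx = _first_sustained(v > v_thresh, sustain, start=int(settle_s * rate_hz))
    if idx is None:
        raise ValueError("belt marker never exceeds the onset velocity threshold")
    return _cross_up(v, idx, v_thresh, rate_hz)


def detect_step_events(heel: np.ndarray, rate_hz: float, bon_s: float,
                       v_thresh: float = 0.05, sustain: int = 3
                       ) -> tuple[float, float]:
    """Recovery-foot liftoff and touchdown from the heel's AP velocity.

    The step shows up as one AP-velocity burst. Liftoff is the upward
    threshold crossing entering the burst and TD the downward crossing
    leaving it, both anchored at the burst peak and sub-frame interpolated
    (zero-phase filtering rings around the step, so a naive first-crossing
    search can trigger on side lobes).
    """
    v = np.abs(_central_velocity(heel[:, AP], rate_hz))
    start = int(np.ceil(bon_s * rate_hz))
    if start >= v.size - 1:
        raise ValueError("belt onset too close to trial end")
    peak = start + int(np.argmax(v[start:]))
    if v[peak] <= 10 * v_thresh:
        raise ValueError("no recovery-foot movement burst found after belt onset")
    below = v < v_thresh
    lift_idx = None
    for i in range(peak, start - 1, -1):
        if below[i]:
            lift_idx = i + 1
            break
    if lift_idx is None:
        raise ValueError("no recovery-foot liftoff found after belt onset")
    after = np.nonzero(below[peak:])[0]
    if after.size == 0:
        raise ValueError("no recovery-foot touchdown found after liftoff")
    td_idx = peak + int(after[0])
    return (_cross_up(v, lift_idx, v_thresh, rate_hz),
            _cross_down(v, td_idx, v_thresh, rate_hz))


def detect_events(markers: MarkerTrial, recovery_side: str = "right",
                  v_thresh: float = 0.05, sustain: int = 3,
                  event_lowpass_hz: Optional[float] = 10.0) -> TrialEvents:
    """BON, liftoff and TD for one trial.

    Events use their own, lighter low-pass (default 10 Hz) than the 6 Hz
    outcome filter: the threshold crossings of a ~0.2 s step are visibly
    smeared at 6 Hz. Pass ``event_lowpass_hz=None`` if ``markers`` are
    already filtered.
    """
    if event_lowpass_hz is not None:
        markers = lowpass_markers(markers, event_lowpass_hz)
    bon = detect_bon(markers.trajectory("belt"), markers.rate_hz, v_thresh, sustain)
    heel = markers.trajectory(f"{recovery_side[0].upper()}_heel")
    lift, td = detect_step_events(heel, markers.rate_hz, bon, v_thresh, sustain)
    return TrialEvents(bon_s=bon, liftoff_s=lift, td_s=td, recovery_side=recovery_side)


def _heel_names(recovery_side: str) -> tuple[str, str]:
    rec = recovery_side[0].upper()
    slip = "L" if rec == "R" else "R"
    return f"{rec}_heel", f"{slip}_heel"


def step_metrics(markers: MarkerTrial, events: TrialEvents
                 ) -> tuple[float, float, float, float]:
    """(initiation s, execution s, step length m, step width m).

    Step length = slipping-heel minus recovery-heel AP distance at TD
    (positive for a backward recovery step); width = |ML difference| at TD.
    """
    initiation = events.liftoff_s - events.bon_s
    execution = events.td_s - events.liftoff_s
    frame = int(round(events.td_s * markers.rate_hz))
    rec_name, slip_name = _heel_names(events.recovery_side)
    rec = markers.trajectory(rec_name)[frame]
    slip = markers.trajectory(slip_name)[frame]
    step_length = slip[AP] - rec[AP]
    step_width = abs(slip[ML] - rec[ML])
    return initiation, execution, float(step_length), float(step_width)


def com_estimate(markers: MarkerTrial,
                 table: Sequence[SegmentRow] = DEFAULT_SEGMENT_TABLE) -> np.ndarray:
    """Whole-body COM trajectory [n_frames x 3] from the segmental model."""
    total = sum(r.mass_fraction for r in table)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"segment mass fractions sum to {total}, expected 1")
    com = np.zeros((markers.n_frames, 3))
    for row in table:
        prox = markers.trajectory(row.proximal)
        dist = markers.trajectory(row.distal)
        com += row.mass_fraction * (prox + row.com_fraction * (dist - prox))
    return com


def com_state(com: np.ndarray, markers: MarkerTrial, events: TrialEvents
              ) -> tuple[float, float, float, float]:
    """COM position (BOS-normalized) and velocity at touchdown.

    AP position: COM minus recovery heel, over BOS length (trailing heel to
    leading toe in AP). ML position: smaller distance from COM to either
    lateral BOS edge (the toes), over BOS width. AP velocity is relative to
    the recovery heel; ML velocity is absolute.
    """
    rate = markers.rate_hz
    frame = int(round(events.td_s * rate))
    rec_name, _ = _heel_names(events.recovery_side)
    heels = np.array([markers.trajectory("L_heel")[frame],
                      markers.trajectory("R_heel")[frame]])
    toes = np.array([markers.trajectory("L_toe")[frame],
                     markers.trajectory("R_toe")[frame]])
    trailing_heel_ap = heels[:, AP].min()
    leading_toe_ap = toes[:, AP].max()
    bos_length = leading_toe_ap - trailing_heel_ap
    if bos_length <= 0:
        raise ValueError("degenerate base of support: non-positive AP length")
    bos_width = abs(toes[0, ML] - toes[1, ML])
    if bos_width <= 0:
        raise ValueError("degenerate base of support: zero ML width")

    rec_heel = markers.trajectory(rec_name)
    ap_norm = (com[frame, AP] - rec_heel[frame, AP]) / bos_length
    ml_edges = sorted([toes[0, ML], toes[1, ML]])
    ml_norm = min(abs(com[frame, ML] - ml_edges[0]),
                  abs(com[frame, ML] - ml_edges[1])) / bos_width

    com_v = _central_velocity(com, rate)
    heel_v = _central_velocity(rec_heel, rate)
    ap_vel = com_v[frame, AP] - heel_v[frame, AP]
    ml_vel = abs(com_v[frame, ML])
    return float(ap_norm), float(ml_norm), float(ap_vel), float(ml_vel)


def trunk_arm_angles(markers: MarkerTrial, events: TrialEvents
                     ) -> tuple[float, float]:
    """Trunk inclination above the transverse plane and max arm flexion at TD.

    Trunk: angle of the hip-midpoint -> shoulder-midpoint vector above the
    horizontal (90 deg = upright, < 90 = flexion). Arm: angle of the
    shoulder -> elbow vector from the downward vertical, larger of the two
    arms.
    """
    frame = int(round(events.td_s * markers.rate_hz))
    sh_mid = 0.5 * (markers.trajectory("L_shoulder")[frame]
                    + markers.trajectory("R_shoulder")[frame])
    hip_mid = 0.5 * (markers.trajectory("L_hip")[frame]
                     + markers.trajectory("R_hip")[frame])
    trunk_vec = sh_mid - hip_mid
    horiz = np.hypot(trunk_vec[AP], trunk_vec[ML])
    if horiz == 0 and trunk_vec[VERT] == 0:
        raise ValueError("coincident shoulder/hip midpoints")
    trunk = np.degrees(np.arctan2(trunk_vec[VERT], trunk_vec[AP]))

    flexions = []
    for side in ("L", "R"):
        sh = markers.trajectory(f"{side}_shoulder")[frame]
        el = markers.trajectory(f"{side}_elbow")[frame]
        v = el - sh
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"coincident {side} shoulder/elbow markers")
        # angle from downward vertical
        cosang = np.clip(-v[VERT] / norm, -1.0, 1.0)
        flexions.append(np.degrees(np.arccos(cosang)))
    return float(trunk), float(max(flexions))


def detect_fall(load: LoadCellTrial, thresh_pct: float = 30.0) -> bool:
    """Fall iff the peak harness force strictly exceeds thresh% of body weight."""
    if load.body_weight_n <= 0:
        raise ValueError("body weight must be positive")
    return bool(load.force.max() > (thresh_pct / 100.0) * load.body_weight_n)


def compute_outcomes(bundle: TrialBundle, marker_lowpass_hz: float = 6.0,
                     v_thresh: float = 0.05, sustain: int = 3,
                     fall_bw_pct: float = 30.0,
                     segment_table: Sequence[SegmentRow] = DEFAULT_SEGMENT_TABLE,
                     events: Optional[TrialEvents] = None
                     ) -> tuple[TrialEvents, KinematicOutcomes]:
    """Full kinematic outcome set for one trial bundle."""
    markers = lowpass_markers(bundle.markers, marker_lowpass_hz)
    if events is None:
        events = detect_events(bundle.markers, bundle.recovery_side, v_thresh, sustain)
    initiation, execution, length, width = step_metrics(markers, events)
    com = com_estimate(markers, segment_table)
    ap_pos, ml_pos, ap_vel, ml_vel = com_state(com, markers, events)
    trunk, arm = trunk_arm_angles(markers, events)
    outcomes = KinematicOutcomes(
        step_initiation_s=initiation, step_execution_s=execution,
        step_length_m=length, step_width_m=width,
        ap_com_pos_norm=ap_pos, ml_com_pos_norm=ml_pos,
        ap_com_vel_mps=ap_vel, ml_com_vel_mps=ml_vel,
        trunk_angle_deg=trunk, arm_flexion_deg=arm,
        fall=detect_fall(bundle.loadcell, fall_bw_pct),
    )
    return events, outcomes
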