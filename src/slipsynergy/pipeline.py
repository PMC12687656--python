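"""End-to-end two-stage analysis of a slip-training cohort.

Per participant and stage (early = S1-S2, late = S9-S10): marker filtering
and event detection, EMG envelope/window/bin/concatenate/normalize, synergy
extraction with VAF dimensionality selection, and 100-point activation
curves. Per stage: pooling, silhouette-selected k-means clustering into
modes, naming and peak-time ordering. Across stages: one-to-one mode
matching by Pearson r (0.83 threshold), per-muscle weight comparisons and
activation-feature comparisons (paired t), plus the kinematic outcome table
with repeated-measures ANOVA over S1, S2, S9, S10 and stage-mean paired
t-tests. All randomness derives from one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering, features, kinematics, preprocess, stats, synergy
from .io_model import (
    CANONICAL_LABELS,
    PipelineConfig,
    Session,
    read_session,
)

log = logging.getLogger("slipsynergy")

__all__ = ["StageReport", "ParticipantStage", "run", "extract_participant_stage"]

STAGES = ("early", "late")
KINEMATIC_VARS = (
    "step_initiation_s", "step_execution_s", "step_length_m", "step_width_m",
    "ap_com_pos_norm", "ml_com_pos_norm", "ap_com_vel_mps", "ml_com_vel_mps",
    "trunk_angle_deg", "arm_flexion_deg",
)


@dataclass
class ParticipantStage:
    """One participant-stage extraction result."""

    participant_id: str
    stage: str
    synergies: synergy.SynergySet           # unit-max W, original scaling
    curves100: np.ndarray                   # [K x 100] mean activation curves
    matrix: preprocess.EnvelopeMatrix


@dataclass
class StageReport:
    kinematics_table: pd.DataFrame
    kinematics_stats: pd.DataFrame
    dimensionality_table: pd.DataFrame
    dimensionality_test: stats.StatsResult
    modes: dict[str, clustering.ClusteredModes]
    match: clustering.ModeMatch
    weight_stats: pd.DataFrame
    feature_table: pd.DataFrame
    feature_stats: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    # stage -> participant -> ParticipantStage (per-participant factorizations)
    extractions: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.kinematics_table.to_csv(out / "kinematics.csv", index=False)
        self.kinematics_stats.to_csv(out / "kinematics_stats.csv", index=False)
        self.dimensionality_table.to_csv(out / "dimensionality.csv", index=False)
        self.weight_stats.to_csv(out / "weight_stats.csv", index=False)
        self.feature_table.to_csv(out / "features.csv", index=False)
        self.feature_stats.to_csv(out / "feature_stats.csv", index=False)
        modes_json = {}
        for stage, m in self.modes.items():
            modes_json[stage] = {
                "chosen_k": m.chosen_k,
                "silhouette_by_k": m.silhouette_by_k,
                "mode_names": m.mode_names,
                "mode_order": m.mode_order,
                "centroids": m.centroids.tolist(),
                "muscle_order": list(CANONICAL_LABELS),
            }
        modes_json["match"] = {
            "pairs": self.match.pairs,
            "unmatched_early": self.match.unmatched_early,
            "unmatched_late": self.match.unmatched_late,
            "threshold": self.match.threshold,
        }
        modes_json["provenance"] = self.provenance
        (out / "modes.json").write_text(json.dumps(
            modes_json, indent=2,
            default=lambda o: o.item() if hasattr(o, "item") else str(o)))


def _trial_events(session: Session, config: PipelineConfig) -> dict[str, kinematics.TrialEvents]:
    events = {}
    for bundle in session.trials:
        events[bundle.trial_id] = kinematics.detect_events(
            bundle.markers, bundle.recovery_side,
            config.belt_velocity_thresh_mps, config.event_sustain_frames,
            config.event_lowpass_hz,
        )
    return events


def extract_participant_stage(session: Session, stage: str, config: PipelineConfig,
                              events: Optional[dict] = None,
                              seed: Optional[int] = None) -> ParticipantStage:
    """Envelope -> window -> bin -> concatenate -> normalize -> NNMF for one stage."""
    if events is None:
        events = _trial_events(session, config)
    if seed is None:
        seed = config.seed

    def binned(bundle) -> preprocess.EnvelopeMatrix:
        ev = events[bundle.trial_id]
        env = preprocess.envelope(bundle.emg, config.emg_highpass_hz, config.emg_lowpass_hz)
        win = preprocess.window(env, ev.bon_s, ev.td_s,
                                config.window_pre_ms, config.window_post_ms)
        return preprocess.bin_average(win, config.bin_ms)

    all_mats = [binned(b) for b in session.trials]
    factors = preprocess.session_norm_factors(all_mats)
    stage_idx = [i for i, b in enumerate(session.trials)
                 if session.stage_map.get(i) == stage]
    if not stage_idx:
        raise ValueError(f"session {session.participant_id} has no {stage!r} trials")
    mat = preprocess.concatenate([all_mats[i] for i in stage_idx])
    mat = preprocess.normalize_max(mat, factors)
    mat = preprocess.scale_unit_variance(mat)

    s = synergy.select_dimensionality(
        mat, k_max=config.k_max_synergies,
        vaf_global_pct=config.vaf_global_pct,
        vaf_muscle_pct=config.vaf_muscle_pct,
        vaf_gain_pct=config.vaf_gain_pct,
        restarts=config.nnmf_restarts, max_iter=config.nnmf_max_iter,
        tol=config.nnmf_tol, seed=seed,
    )
    s = synergy.unscale_and_normalize(s, mat.unit_var_scales)

    # per-synergy activation: each trial's block time-normalized to 100
    # points, averaged over the stage's trials
    bounds = list(mat.trial_boundaries) + [mat.n_bins]
    curves = np.zeros((s.k, config.curve_points))
    for j in range(s.k):
        segs = [features.time_normalize(s.C[j, a:b], config.curve_points)
                for a, b in zip(bounds[:-1], bounds[1:])]
        curves[j] = np.mean(segs, axis=0)
    return ParticipantStage(session.participant_id, stage, s, curves, mat)


def _kinematics_tables(sessions: Sequence[Session], config: PipelineConfig,
                       all_events: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for session in sessions:
        for i, bundle in enumerate(session.trials):
            stage = session.stage_map.get(i, "other")
            if stage not in STAGES:
                continue
            ev = all_events[session.participant_id][bundle.trial_id]
            _, out = kinematics.compute_outcomes(
                bundle, config.marker_lowpass_hz,
                config.heel_velocity_thresh_mps, config.event_sustain_frames,
                config.fall_bw_pct, events=ev,
            )
            row = {"participant": session.participant_id, "trial": bundle.trial_id,
                   "stage": stage, "fall": out.fall}
            row.update({v: getattr(out, v) for v in KINEMATIC_VARS})
            rows.append(row)
    table = pd.DataFrame(rows)

    stat_rows = []
    trial_order = sorted(table["trial"].unique())
    for var in KINEMATIC_VARS:
        wide = table.pivot_table(index="participant", columns="trial", values=var)
        wide = wide.reindex(columns=trial_order).dropna()
        anova = stats.rm_anova(wide.to_numpy())
        early = wide[[t for t in trial_order if t in ("S1", "S2")]].mean(axis=1)
        late = wide[[t for t in trial_order if t in ("S9", "S10")]].mean(axis=1)
        diffs = (early - late).to_numpy()
        ks_p = stats.ks_normality(diffs).p if diffs.size >= 4 else np.nan
        t = stats.paired_t(early.to_numpy(), late.to_numpy())
        stat_rows.append({
            "variable": var,
            "early_mean": early.mean(), "late_mean": late.mean(),
            "ks_p": ks_p,
            "anova_F": anova.statistic, "anova_df1": anova.df[0],
            "anova_df2": anova.df[1], "anova_p": anova.p,
            "t": t.statistic, "t_df": t.df[0], "t_p": t.p,
            "cohens_d": t.effect_size_d,
        })
    return table, pd.DataFrame(stat_rows)


def run(sessions: Sequence[Session] | str | Path,
        config: Optional[PipelineConfig] = None,
        out_dir: Optional[str | Path] = None) -> StageReport:
    """Run the full two-stage analysis over a cohort.

    ``sessions`` is either a list of in-memory sessions or a directory of
    session subdirectories (each with a session.yaml).
    """
    config = config or PipelineConfig()
    if isinstance(sessions, (str, Path)):
        root = Path(sessions)
        dirs = sorted(d for d in root.iterdir() if (d / "session.yaml").exists())
        if not dirs:
            raise FileNotFoundError(f"no session directories under {root}")
        sessions = [read_session(d) for d in dirs]

    log.info("analyzing %d sessions", len(sessions))
    all_events: dict[str, dict] = {}
    extractions: dict[str, dict[str, ParticipantStage]] = {s: {} for s in STAGES}
    for p_i, session in enumerate(sessions):
        try:
            events = _trial_events(session, config)
            all_events[session.participant_id] = events
            for s_i, stage in enumerate(STAGES):
                ps = extract_participant_stage(
                    session, stage, config, events,
                    seed=config.seed + 1000 * p_i + 100 * s_i,
                )
                extractions[stage][session.participant_id] = ps
                log.info("%s %s: K=%d (VAF %.1f%%)", session.participant_id,
                         stage, ps.synergies.k, ps.synergies.vaf_global)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for participant {session.participant_id}: {exc}"
            ) from exc

    # dimensionality table + Wilcoxon
    pids = [s.participant_id for s in sessions]
    dims = pd.DataFrame({
        "participant": pids,
        "early": [extractions["early"][p].synergies.k for p in pids],
        "late": [extractions["late"][p].synergies.k for p in pids],
    })
    dim_test = stats.wilcoxon_signed_rank(dims["early"], dims["late"])

    # pooling, clustering, naming per stage
    modes: dict[str, clustering.ClusteredModes] = {}
    curve_lookup: dict[str, dict[tuple[str, int], np.ndarray]] = {}
    for stage in STAGES:
        pairs = [(p, extractions[stage][p].synergies) for p in pids]
        pooled = clustering.pool(pairs, stage=stage)
        m = clustering.cluster_stage(
            pooled, k=None, k_min=config.cluster_k_min, k_max=config.cluster_k_max,
            n_init=config.kmeans_repeats, seed=config.seed,
        )
        lookup = {}
        for p in pids:
            ps = extractions[stage][p]
            for j in range(ps.synergies.k):
                lookup[(p, j)] = ps.curves100[j]
        curve_lookup[stage] = lookup
        mean_act = np.vstack([
            np.mean([lookup[lab] for lab, a in zip(m.labels, m.assignments)
                     if a == mode], axis=0)
            for mode in range(m.chosen_k)
        ])
        modes[stage] = clustering.name_and_order(m, mean_act)
        log.info("%s stage: %d modes %s", stage, m.chosen_k, m.mode_names)

    match = clustering.match_stages(modes["early"], modes["late"],
                                    threshold=config.similarity_r)

    # per-muscle weight comparisons within matched modes
    weight_results = clustering.compare_mode_weights(modes["early"], modes["late"], match)
    w_rows = []
    for (i, j), res_list in weight_results.items():
        for mus, res in enumerate(res_list):
            w_rows.append({
                "early_mode": modes["early"].mode_names[i],
                "late_mode": modes["late"].mode_names[j],
                "muscle": CANONICAL_LABELS[mus],
                "t": res.statistic, "df": res.df[0], "p": res.p,
                "cohens_d": res.effect_size_d, "n_pairs": res.n,
            })
    weight_stats = pd.DataFrame(w_rows)

    # activation features per mode and stage
    f_rows, fs_rows = [], []
    for i, j, r in match.pairs:
        per_stage_feats: dict[str, dict[str, features.ActivationFeatures]] = {}
        for stage, mode in (("early", i), ("late", j)):
            m = modes[stage]
            by_pid: dict[str, list[np.ndarray]] = {}
            for lab, a in zip(m.labels, m.assignments):
                if a == mode:
                    by_pid.setdefault(lab[0], []).append(curve_lookup[stage][lab])
            per_stage_feats[stage] = {
                pid: features.extract_features(np.mean(cs, axis=0),
                                               config.curve_points, config.onset_pct)
                for pid, cs in by_pid.items()
            }
            for pid, f in per_stage_feats[stage].items():
                f_rows.append({
                    "mode": m.mode_names[mode], "stage": stage, "participant": pid,
                    "peak_amp": f.peak_amp, "area": f.area,
                    "peak_time_pct": f.peak_time_pct, "onset_pct": f.onset_pct,
                })
        shared = sorted(set(per_stage_feats["early"]) & set(per_stage_feats["late"]))
        if len(shared) >= 3:
            res = features.compare_features(
                [per_stage_feats["early"][p] for p in shared],
                [per_stage_feats["late"][p] for p in shared],
            )
            for fname, r_ in res.items():
                fs_rows.append({
                    "early_mode": modes["early"].mode_names[i],
                    "late_mode": modes["late"].mode_names[j],
                    "feature": fname, "t": r_.statistic, "df": r_.df[0],
                    "p": r_.p, "cohens_d": r_.effect_size_d, "n_pairs": r_.n,
                })
    feature_table = pd.DataFrame(f_rows)
    feature_stats = pd.DataFrame(fs_rows)

    kin_table, kin_stats = _kinematics_tables(sessions, config, all_events)

    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True)
    report = StageReport(
        kinematics_table=kin_table, kinematics_stats=kin_stats,
        dimensionality_table=dims, dimensionality_test=dim_test,
        modes=modes, match=match, weight_stats=weight_stats,
        feature_table=feature_table, feature_stats=feature_stats,
        extractions=extractions,
        provenance={
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "n_participants": len(sessions),
            "seed": config.seed,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
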