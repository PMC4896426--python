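"""End-to-end orchestration: simulate/load -> preprocess -> connectivity ->
communities -> co-occurrence -> node metrics -> brain-behavior CCA.

A :class:`RunConfig` holds every knob with defaults matching the standard
analysis settings (discard 20 frames, high-pass 0.008 Hz, 40 s windows with
step 1 and theta = T/3, 100 community initializations, 4 CV folds, 10,000
permutations). One master seed is fanned out to named sub-streams (stage,
session, subject) so identical configs reproduce identical numbers and
partial reruns are stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as tsio
from .behavior import CcaResult, cv_cca, permutation_p
from .community import (CoOccurrence, Partition, co_occurrence,
                        detect_communities_stack, reference_partition)
from .connectivity import WindowSpec, sliding_connectivity, static_connectivity
from .metrics import high_flex_cluster, node_dynamics_table, session_overlap
from .simulate import BehaviorSpec, SimSpec, make_atlas, simulate_behavior, simulate_cohort

__all__ = ["RunConfig", "SessionResult", "RunResult", "run_pipeline", "compare_sessions"]

log = logging.getLogger("dynfc")

# named sub-streams of the master seed
_STREAM_REF = 1
_STREAM_WINDOWS = 2
_STREAM_CLUSTER = 3
_STREAM_BEHAVIOR = 4
_STREAM_CCA = 5


def _substream(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``sim`` (synthetic cohort) or ``signal_paths`` (delimited text
    files, one per subject) must be given.
    """

    sim: SimSpec | None = None
    n_subjects: int = 20
    sessions: int = 1
    signal_paths: tuple[str, ...] | None = None
    dt: float = 0.72
    discard_frames: int = 20
    highpass_hz: float = 0.008
    window_s: float = 40.0
    step_frames: int = 1
    theta_fraction: float = 1.0 / 3.0
    n_init: int = 100
    behavior: BehaviorSpec | None = None
    cca_folds: int = 4
    n_perm: int = 10000
    seed: int = 0
    out_dir: str | None = None

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_s, self.step_frames, self.theta_fraction)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class SessionResult:
    session: int
    signals: tsio.SignalSet
    static: np.ndarray
    reference: Partition
    cooccurrence: dict[str, CoOccurrence]
    node_table: pd.DataFrame
    cluster: list[str]
    cluster_summary: pd.DataFrame


@dataclass
class RunResult:
    config: RunConfig
    atlas: pd.DataFrame | None
    sessions: list[SessionResult]
    brain_measure: pd.Series | None
    behavior: pd.DataFrame | None
    cca: CcaResult | None
    manifest: dict


def _analyze_session(
    signals: tsio.SignalSet,
    config: RunConfig,
    atlas: pd.DataFrame | None,
    session: int,
) -> SessionResult:
    stage = "preprocess"
    try:
        s = tsio.discard_initial_frames(signals, config.discard_frames)
        s = tsio.highpass(s, config.highpass_hz)
        stage = "static connectivity"
        static = static_connectivity(s)
        stage = "reference partition"
        ref = reference_partition(static, n_init=config.n_init,
                                  seed=_substream(config.seed, _STREAM_REF, session))
        stage = "windowed connectivity/communities"
        wspec = config.window_spec()
        stacks = sliding_connectivity(s, wspec)
        cooc: dict[str, CoOccurrence] = {}
        for j, (subj, stack) in enumerate(zip(s.subjects, stacks)):
            parts = detect_communities_stack(
                stack, n_init=config.n_init,
                seed=_substream(config.seed, _STREAM_WINDOWS, session, j))
            cooc[subj] = co_occurrence(parts, subject=subj)
            log.info("session %d: subject %s: %d windows", session, subj, len(parts))
        stage = "node metrics"
        table = node_dynamics_table(cooc, ref, static, list(s.node_ids), atlas)
        stage = "high-flexibility cluster"
        cluster, summary = high_flex_cluster(
            table, seed=_substream(config.seed, _STREAM_CLUSTER, session))
    except Exception as exc:
        raise RuntimeError(f"session {session}: stage '{stage}' failed: {exc}") from exc
    return SessionResult(session, s, static, ref, cooc, table, cluster, summary)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages; optionally write artifacts + manifest to out_dir."""
    if (config.sim is None) == (config.signal_paths is None):
        raise ValueError("exactly one of sim / signal_paths must be set")
    if config.sim is not None:
        log.info("simulating cohort: %d subjects, %d sessions", config.n_subjects, config.sessions)
        cohorts = simulate_cohort(config.sim, config.n_subjects, config.sessions)
        atlas = make_atlas(config.sim)
    else:
        cohorts = [tsio.load_signals(config.signal_paths, config.dt)]
        atlas = None

    sessions = [
        _analyze_session(signals, config, atlas, i) for i, signals in enumerate(cohorts)
    ]

    brain = behavior_table = cca = None
    first = sessions[0]
    flex = first.node_table[first.node_table["node"].isin(first.cluster)]
    if len(flex):
        brain = flex.groupby("subject", sort=False)["flexibility"].mean()
        brain = brain.reindex(first.signals.subjects)
    if config.behavior is not None and brain is not None:
        behavior_table = simulate_behavior(config.behavior, brain)
        cca = permutation_p(
            brain.to_numpy(), behavior_table, k=config.cca_folds,
            n_perm=config.n_perm, seed=_substream(config.seed, _STREAM_CCA))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_sessions": len(sessions),
        "n_windows": int(sessions[0].cooccurrence[first.signals.subjects[0]].n_windows),
        "high_flex_cluster": {s.session: s.cluster for s in sessions},
        "warnings": [],
    }
    result = RunResult(config, atlas, sessions, brain, behavior_table, cca, manifest)
    if config.out_dir is not None:
        _write_artifacts(result, Path(config.out_dir))
    return result


def _write_artifacts(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for s in result.sessions:
        tag = f"session{s.session}"
        s.node_table.to_csv(out / f"node_dynamics_{tag}.csv", index=False)
        pd.DataFrame(
            {"node_id": list(s.signals.node_ids), "community": s.reference.labels}
        ).to_csv(out / f"reference_partition_{tag}.csv", index=False)
        cdir = out / f"cooccurrence_{tag}"
        cdir.mkdir(exist_ok=True)
        for subj, C in s.cooccurrence.items():
            np.savetxt(cdir / f"{subj}.csv", C.C, delimiter=",")
    if result.atlas is not None:
        result.atlas.to_csv(out / "atlas.csv", index=False)
    if result.behavior is not None:
        result.behavior.to_csv(out / "behavior.csv")
    manifest = dict(result.manifest)
    if result.cca is not None:
        manifest["cca"] = {"rho": result.cca.rho, "p": result.cca.p,
                           "n_permutations": result.cca.n_permutations}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def compare_sessions(run_a: SessionResult, run_b: SessionResult) -> dict:
    """Test-retest similarity between two sessions of the same cohort.

    Per subject: Pearson correlation between the vectorized upper triangles
    of the session co-occurrence matrices; reported with a one-sample
    two-sided t-test of the Fisher-z similarities against 0, plus the
    bidirectional overlap of the high-flexibility clusters.
    """
    subjects = [s for s in run_a.cooccurrence if s in run_b.cooccurrence]
    if not subjects:
        raise ValueError("sessions share no subjects")
    n = run_a.cooccurrence[subjects[0]].C.shape[0]
    iu = np.triu_indices(n, k=1)
    sims = []
    for subj in subjects:
        a = run_a.cooccurrence[subj].C[iu]
        b = run_b.cooccurrence[subj].C[iu]
        if a.std() == 0 or b.std() == 0:
            sims.append(np.nan)
            continue
        sims.append(float(np.corrcoef(a, b)[0, 1]))
    sims = np.asarray(sims)
    valid = sims[~np.isnan(sims)]
    if len(valid) > 1 and valid.std() > 0:
        t, p = stats.ttest_1samp(np.arctanh(np.clip(valid, -1 + 1e-12, 1 - 1e-12)), 0.0)
    else:
        t, p = np.nan, np.nan
    ov_ab, ov_ba = session_overlap(run_a.cluster, run_b.cluster)
    return {
        "per_subject_r": pd.Series(sims, index=subjects),
        "mean_r": float(np.nanmean(sims)),
        "t_vs_zero": float(t),
        "p_vs_zero": float(p),
        "cluster_overlap_a_in_b": ov_ab,
        "cluster_overlap_b_in_a": ov_ba,
    }
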