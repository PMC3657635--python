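"""End-to-end experiment orchestration from a single seeded configuration.

Stages: simulate navigation trials (maze -> trials -> tracks -> rendered
scenes -> 73 behavioral variables), synthesize ROI voxel runs, normalize
and align them, decode every variable x ROI under leave-one-trial-out
cross-validation, rank candidate tracks per source x ROI, fuse rankings
with calibration-derived weights, and evaluate against the white-matter
empirical null.  Every random draw flows from the config seed through
deterministic per-stage seed derivations, so a rerun of the same config
reproduces the experiment exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mazedecode import decode as dec
from mazedecode import features as feat
from mazedecode import maze_world as mw
from mazedecode import ranking as rk
from mazedecode import signal_prep as sp
from mazedecode import stats_eval as se
from mazedecode import synth_fmri as sf

logger = logging.getLogger(__name__)


def _derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31 from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Everything that defines a synthetic experiment.

    All randomness is derived from ``seed``; the config round-trips through
    JSON losslessly.
    """

    seed: int = 0
    n_sessions: int = 2
    trials_per_session: int = 12
    resolution: tuple[int, int] = (72, 96)
    fov: float = 60.0
    turn_rate: float = 6.0
    detour_prob: float = 0.25
    duration_bounds_s: tuple[float, float] = (57.0, 195.0)
    snr: float = 3.0
    rois: tuple[str, ...] = ("V1", "Ve", "Pa", "M1", "PM", "Hi", "WM")
    sources: tuple[str, ...] = feat.SOURCES
    lag_trs: int = 2
    pool: str = "all"  # "all" or "session"
    weights_split: str = "other-session"  # or "same"
    maze_path: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExperimentConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = json.loads(text)
        for key in ("resolution", "duration_bounds_s", "rois", "sources"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_fixture(seed: int = 0) -> ExperimentConfig:
    """A desk-scale experiment: 2 sessions x 6 trials, 3 ROIs (one visual,
    one motor, the white-matter control), reduced renderer resolution."""
    return ExperimentConfig(
        seed=seed,
        n_sessions=2,
        trials_per_session=6,
        resolution=(48, 64),
        snr=6.0,
        rois=("V1", "M1", "WM"),
    )


# ---------------------------------------------------------------------------
# stage 1: behavior


@dataclass
class BehavioralData:
    maze: mw.MazeMap
    trials: list[mw.TrialSpec]
    tracks: list[mw.Track]
    variable_sets: list[feat.VariableSet]
    session_of: list[int]


def simulate_behavior(config: ExperimentConfig) -> BehavioralData:
    """Generate all trials' tracks and variables.

    Routes whose simulated duration falls outside ``duration_bounds_s`` are
    re-planned with adapted detour probability (longer routes need more
    detours) for a bounded number of attempts.
    """
    maze = mw.load_maze(config.maze_path) if config.maze_path else mw.default_maze()
    lo, hi = config.duration_bounds_s
    trials, tracks, varsets, session_of = [], [], [], []
    for sess in range(config.n_sessions):
        for k in range(config.trials_per_session):
            track = trial = None
            for attempt in range(8):
                s = _derive_seed(config.seed, sess, k, attempt)
                trial = mw.sample_trial(maze, s)
                dp = config.detour_prob * (1.0 + 0.5 * attempt)
                rng = np.random.default_rng(_derive_seed(s, 1))
                path = mw.plan_route(maze, trial, detour_prob=min(dp, 0.9), rng=rng)
                track = mw.simulate_track(path, trial, config.turn_rate, maze=maze)
                if lo <= track.duration_seconds <= hi:
                    break
            assert track is not None and trial is not None
            scenes = mw.render_track(maze, track, config.resolution, config.fov)
            varsets.append(feat.build_variable_set(track, scenes))
            trials.append(trial)
            tracks.append(track)
            session_of.append(sess)
    return BehavioralData(maze, trials, tracks, varsets, session_of)


# ---------------------------------------------------------------------------
# stage 2-3: scanner stand-in + preparation


def synthesize_and_prepare(
    config: ExperimentConfig, behavior: BehavioralData
) -> dict[str, list[sp.AlignedTrial]]:
    """Per ROI: synthesize one run per session, normalize, align; return the
    aligned trials concatenated across sessions in global trial order."""
    profiles = sf.default_roi_profiles(config.snr, seed=_derive_seed(config.seed, 101),
                                       rois=config.rois, lag_trs=config.lag_trs)
    aligned: dict[str, list[sp.AlignedTrial]] = {roi: [] for roi in config.rois}
    for sess in range(config.n_sessions):
        idx = [i for i, s in enumerate(behavior.session_of) if s == sess]
        vsets = [behavior.variable_sets[i] for i in idx]
        for roi_idx, roi in enumerate(config.rois):
            run = sf.synthesize_run(
                profiles[roi], vsets,
                # stable per-ROI seed component (str hash() varies by process)
                seed=_derive_seed(config.seed, 202, sess, roi_idx),
                run_id=f"sess{sess}",
            )
            prepared = sp.normalize_run(run)
            for at, gi in zip(sp.align_to_variables(prepared, vsets, config.lag_trs), idx):
                at.trial_index = gi
                aligned[roi].append(at)
    for roi in aligned:
        aligned[roi].sort(key=lambda t: t.trial_index)
    return aligned


# ---------------------------------------------------------------------------
# stage 4-5: decode + rank


def decode_experiment(
    config: ExperimentConfig, aligned: dict[str, list[sp.AlignedTrial]]
) -> dict[str, dict[str, dict[str, dec.LotoResult]]]:
    """roi -> source -> variable_id -> LotoResult."""
    out: dict[str, dict[str, dict[str, dec.LotoResult]]] = {}
    for roi, trials in aligned.items():
        out[roi] = {}
        for source in config.sources:
            out[roi][source] = dec.decode_source(
                trials, source, roi=roi, seed=_derive_seed(config.seed, 303))
    return out


def predictions_by_trial(
    results: dict[str, dec.LotoResult], n_trials: int
) -> list[dict[str, np.ndarray]]:
    """Re-index decoder output as per-trial {variable_id: predicted trace}."""
    per_trial: list[dict[str, np.ndarray]] = [dict() for _ in range(n_trials)]
    for vid, res in results.items():
        for pred in res.predictions:
            per_trial[pred.trial_index][vid] = pred.values
    return per_trial


def rank_experiment(
    config: ExperimentConfig,
    behavior: BehavioralData,
    decoded: dict[str, dict[str, dict[str, dec.LotoResult]]],
) -> tuple[rk.TrackLibrary, dict[str, list[rk.RankStats]]]:
    """Rank the candidate pool for every trial and source x ROI combination.

    Returns the track library and a mapping "source|roi" -> per-trial
    RankStats (trial order = global trial order).
    """
    library = rk.TrackLibrary(behavior.variable_sets)
    n = len(behavior.trials)
    if config.pool == "session":
        # each trial ranked only among its own session's tracks
        session_lib = {}
        for sess in set(behavior.session_of):
            idx = [i for i in range(n) if behavior.session_of[i] == sess]
            session_lib[sess] = (idx, rk.TrackLibrary(
                [behavior.variable_sets[i] for i in idx]))

    combos: dict[str, list[rk.RankStats]] = {}
    for roi, by_source in decoded.items():
        for source, results in by_source.items():
            preds = predictions_by_trial(results, n)
            if config.pool == "session":
                stats = []
                for i in range(n):
                    idx, lib = session_lib[behavior.session_of[i]]
                    stats.append(rk.rank_tracks(preds[i], source, lib,
                                                correct_index=idx.index(i)))
            else:
                stats = [rk.rank_tracks(preds[i], source, library, correct_index=i)
                         for i in range(n)]
            combos[f"{source}|{roi}"] = stats
    return library, combos


# ---------------------------------------------------------------------------
# stage 6: evaluate


@dataclass
class RunResult:
    config: ExperimentConfig
    behavior: BehavioralData
    decoded: dict
    library: rk.TrackLibrary
    combos: dict[str, list[rk.RankStats]]
    weights: rk.CombinationWeights
    combined: list[rk.RankStats]
    eval_trials: list[int]
    report: se.EvaluationReport


def evaluate(config: ExperimentConfig, behavior: BehavioralData,
             combos: dict[str, list[rk.RankStats]]) -> tuple[
                 rk.CombinationWeights, list[rk.RankStats], list[int], se.EvaluationReport]:
    """Weights from the calibration split, combination on the evaluation
    split, significance against the white-matter null."""
    n = len(behavior.trials)
    wm_keys = [k for k in combos if k.endswith("|WM")]
    info_keys = [k for k in combos if not k.endswith("|WM")]
    if config.weights_split == "other-session" and config.n_sessions > 1:
        calib = [i for i in range(n) if behavior.session_of[i] == 0]
        evalt = [i for i in range(n) if behavior.session_of[i] != 0]
    else:
        calib = evalt = list(range(n))

    weights = rk.combination_weights(
        {k: [combos[k][i] for i in calib] for k in info_keys})
    if sum(weights.weights.values()) > 0:
        fuse_weights: dict[str, float] = weights.weights
    else:  # nothing beat chance on the calibration split: agnostic fusion
        logger.info("all combination weights zero; falling back to equal weights")
        fuse_weights = {k: 1.0 for k in info_keys}
    combined = [rk.combine_rankings({k: combos[k][i] for k in info_keys}, fuse_weights)
                for i in evalt]

    # the null sample is one value per non-informative source x session
    # combination: the mean normalized correct-track rank across its trials
    null_vals = []
    for k in wm_keys:
        for sess in range(config.n_sessions):
            idx = [i for i in range(n) if behavior.session_of[i] == sess]
            null_vals.append(float(np.mean([combos[k][i].normalized for i in idx])))
    if len(null_vals) >= 10:
        null = se.build_null(null_vals)
    else:  # no WM control in this config: fall back to the theoretical null
        null = se.NullDistribution(np.array([0.5]), 0.5, 0.068)
    thr = se.significance_threshold(null)

    per_comb = {}
    for k, stats in combos.items():
        mean_rank = float(np.mean([rs.correct_rank for rs in stats]))
        norm = float(np.mean([rs.normalized for rs in stats]))
        per_comb[k] = {"mean_rank": mean_rank, "normalized": norm,
                       "significant": bool(norm <= thr)}
    report = se.EvaluationReport(
        per_combination=per_comb,
        null_mean=null.mean, null_sd=null.sd, threshold=thr,
        nr_tracks=len(behavior.trials),
        combined_mean_rank=float(np.mean([rs.correct_rank for rs in combined])),
        combined_normalized=float(np.mean([rs.normalized for rs in combined])),
        combined_identification_pct=se.identification_accuracy(combined),
        weights=weights.weights,
    )
    return weights, combined, evalt, report


def run_pipeline(config: ExperimentConfig, out_dir: str | Path | None = None) -> RunResult:
    """Run every stage and, optionally, write artifacts to ``out_dir``."""
    logger.info("stage 1: simulating %d trials", config.n_sessions * config.trials_per_session)
    behavior = simulate_behavior(config)
    logger.info("stage 2: synthesizing %d ROIs", len(config.rois))
    aligned = synthesize_and_prepare(config, behavior)
    logger.info("stage 3: decoding %d sources x %d ROIs", len(config.sources), len(config.rois))
    decoded = decode_experiment(config, aligned)
    logger.info("stage 4: ranking")
    library, combos = rank_experiment(config, behavior, decoded)
    logger.info("stage 5: evaluating")
    weights, combined, evalt, report = evaluate(config, behavior, combos)
    result = RunResult(config, behavior, decoded, library, combos, weights,
                       combined, evalt, report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        report.to_json(out / "report.json")
        (out / "report.txt").write_text(report.to_text())
        rk.rankings_to_frame(
            {str(i): {k: combos[k][i] for k in combos} for i in range(len(behavior.trials))},
            library,
        ).to_csv(out / "rankings.tsv", sep="\t", index=False)
        for i, track in enumerate(behavior.tracks):
            track.to_tsv(out / f"track_{i:03d}.tsv")
    return result
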