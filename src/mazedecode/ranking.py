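"""Track ranking by sum-of-squares mismatch and weighted rank combination.

To decide which candidate track was navigated, each information source's
predicted probability traces are compared against the *actual* variable
traces of every candidate track.  Per variable, predicted and actual
vectors are linearly resampled to a common length (the TR count of the
longest track in the pool), standardized separately to mean 0 / variance 1,
concatenated across the source's variables, and scored by

    SS_diff = sum_t (pred_t - act_t)^2 .

Candidates are ranked by SS_diff (smallest = rank 1, midranks on ties); a
random ranking has expected correct-track rank (nrTracks + 1)/2, so the
normalized rank rank/(nrTracks + 1) equals 0.5 at chance.

Rankings from several source x ROI combinations are fused by a weighted
average of rank vectors, the weight of a combination being an inverse
linear function of its mean correct-track rank on calibration data: rank 1
maps to weight 1, chance rank to weight 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from mazedecode.features import VariableSet


def resample_linear(series: np.ndarray, target_length: int) -> np.ndarray:
    """Resample to ``target_length`` points by linear interpolation on a
    uniform grid; endpoints are preserved."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("cannot resample a series shorter than 2 points")
    if target_length < 2:
        raise ValueError("target length must be at least 2")
    if target_length == x.size:
        return x.copy()
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, target_length)
    return np.interp(dst, src, x)


def standardize(vector: np.ndarray) -> np.ndarray:
    """Scale to mean 0, variance 1 (population); constant input maps to
    zeros so that degenerate variables stay neutral rather than erroring."""
    x = np.asarray(vector, dtype=float)
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - mu) / sd


def ss_diff(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Sum of squared differences between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    return float(((p - a) ** 2).sum())


def chance_rank(nr_tracks: int) -> float:
    """Expected correct-track rank of a random ranking: (n + 1) / 2."""
    if nr_tracks < 1:
        raise ValueError("need at least one track")
    return (nr_tracks + 1) / 2.0


def normalized_rank(rank: float, nr_tracks: int) -> float:
    """rank / (n + 1); equals 0.5 at chance, bounded in (0, 1)."""
    if not 1 <= rank <= nr_tracks:
        raise ValueError(f"rank {rank} outside 1..{nr_tracks}")
    return rank / (nr_tracks + 1.0)


@dataclass
class TrackLibrary:
    """The candidate pool: each track's actual per-TR variable traces.

    All tracks carry the same 73-variable roster; ``common_length`` is the
    TR count of the longest track and is the length every trace is
    resampled to before comparison.
    """

    variable_sets: list[VariableSet]
    track_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variable_sets:
            raise ValueError("track library is empty")
        if not self.track_ids:
            self.track_ids = [f"track{i}" for i in range(len(self.variable_sets))]
        if len(self.track_ids) != len(self.variable_sets):
            raise ValueError("track_ids length mismatch")

    def __len__(self) -> int:
        return len(self.variable_sets)

    @property
    def common_length(self) -> int:
        return max(vs.n_trs for vs in self.variable_sets)


@dataclass
class RankStats:
    """Ranking of one candidate pool for one trial."""

    ss_diff: np.ndarray
    ranks: np.ndarray
    correct_index: int
    nr_tracks: int

    @property
    def correct_rank(self) -> float:
        return float(self.ranks[self.correct_index])

    @property
    def normalized(self) -> float:
        return normalized_rank(self.correct_rank, self.nr_tracks)


def rank_tracks(
    predictions: Mapping[str, np.ndarray],
    source: str,
    library: TrackLibrary,
    correct_index: int,
    max_trs: int | None = None,
) -> RankStats:
    """Rank every candidate track against one trial's predicted traces.

    ``predictions`` maps variable_id -> predicted per-TR values for each
    variable of ``source`` (the held-out trial's calibrated decoder
    output).  Per variable, predicted and actual vectors are resampled to
    the library's common length and standardized separately; the per-
    candidate SS_diff is accumulated over the concatenated variables.
    ``max_trs`` truncates both predicted and actual traces to their first
    ``max_trs`` TRs before resampling (used for time-window analyses).
    """
    if not 0 <= correct_index < len(library):
        raise ValueError("correct track must be part of the pool")
    L = library.common_length if max_trs is None else min(library.common_length, max_trs)
    L = max(L, 2)

    var_ids = [s.variable_id for s in library.variable_sets[0].by_source(source)]
    pred_std: dict[str, np.ndarray] = {}
    for vid in var_ids:
        p = np.asarray(predictions[vid], dtype=float)
        if max_trs is not None:
            p = p[:max_trs]
        pred_std[vid] = standardize(resample_linear(p, L))

    ss = np.empty(len(library))
    for k, vs in enumerate(library.variable_sets):
        total = 0.0
        for vid in var_ids:
            a = vs.get(source, vid).values
            if max_trs is not None:
                a = a[:max_trs]
            a_std = standardize(resample_linear(a, L))
            total += ss_diff(pred_std[vid], a_std)
        ss[k] = total
    ranks = rankdata(ss, method="average")
    return RankStats(ss, ranks, correct_index, len(library))


# ---------------------------------------------------------------------------
# combination across source x ROI


@dataclass
class CombinationWeights:
    """Per source x ROI combination: calibration mean correct-track rank and
    the derived weight max(0, (R_chance - mean_rank) / (R_chance - 1))."""

    mean_ranks: dict[str, float]
    nr_tracks: int
    weights: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        rc = chance_rank(self.nr_tracks)
        denom = rc - 1.0
        self.weights = {}
        for key, mr in self.mean_ranks.items():
            w = 1.0 if denom == 0 else (rc - mr) / denom
            self.weights[key] = float(max(0.0, min(1.0, w)))


def combination_weights(rank_stats: Mapping[str, Sequence[RankStats]]) -> CombinationWeights:
    """Derive combination weights from calibration rankings (one list of
    per-trial RankStats per source x ROI combination)."""
    pools = {rs.nr_tracks for stats in rank_stats.values() for rs in stats}
    if len(pools) != 1:
        raise ValueError("all combinations must rank the same candidate pool")
    mean_ranks = {key: float(np.mean([rs.correct_rank for rs in stats]))
                  for key, stats in rank_stats.items()}
    return CombinationWeights(mean_ranks, pools.pop())


def combine_rankings(
    per_combination: Mapping[str, RankStats],
    weights: CombinationWeights | Mapping[str, float],
) -> RankStats:
    """Fuse one trial's rankings across combinations by weighted averaging.

    Per candidate, the combined score is the weighted mean of its ranks
    over combinations; candidates are then re-ranked by this score
    (midranks on ties).
    """
    w = weights.weights if isinstance(weights, CombinationWeights) else dict(weights)
    keys = [k for k in per_combination if w.get(k, 0.0) > 0.0]
    total = sum(w[k] for k in keys)
    if total <= 0:
        raise ValueError("all combination weights are zero")
    sizes = {per_combination[k].nr_tracks for k in per_combination}
    correct = {per_combination[k].correct_index for k in per_combination}
    if len(sizes) != 1 or len(correct) != 1:
        raise ValueError("combinations disagree on the candidate pool")
    n = sizes.pop()
    score = np.zeros(n)
    for k in keys:
        score += w[k] * per_combination[k].ranks
    score /= total
    ranks = rankdata(score, method="average")
    return RankStats(score, ranks, correct.pop(), n)


def rankings_to_frame(per_trial: Mapping[str, Mapping[str, RankStats]],
                      library: TrackLibrary) -> pd.DataFrame:
    """Long-format export: trial, combination, candidate, ss_diff, rank."""
    rows = []
    for trial, combos in per_trial.items():
        for combo, rs in combos.items():
            for k, tid in enumerate(library.track_ids):
                rows.append((trial, combo, tid, rs.ss_diff[k], rs.ranks[k]))
    return pd.DataFrame(rows, columns=["trial", "combination", "candidate_track",
                                       "ss_diff", "rank"])
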