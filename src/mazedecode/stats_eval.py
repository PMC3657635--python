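"""Empirical-null significance machinery and evaluation summaries.

Because candidate pools and classifier outputs violate simple parametric
assumptions, significance of track decoding is judged against an empirical
null built from non-informative decodings (a white-matter control region):
the distribution of normalized correct-track ranks obtained where no signal
exists.  Decoding counts as significant when the normalized rank falls
below mean - 2.4 SD of that null (~ p = 0.01 under a normal fit).

Also here: the mean-of-k resampling used to assess combined (averaged)
values against the null, the rank-versus-time-window curve, the
foil-similarity analysis, and the percent of trials identified exactly
(correct-track rank 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from mazedecode.ranking import (
    RankStats,
    TrackLibrary,
    rank_tracks,
    resample_linear,
    ss_diff,
    standardize,
)


@dataclass
class NullDistribution:
    """Normalized correct-track ranks from non-informative decodings."""

    values: np.ndarray
    mean: float
    sd: float

    @property
    def normal_fit(self) -> tuple[float, float]:
        return (self.mean, self.sd)


def build_null(noninformative_results: Sequence[float], min_values: int = 10) -> NullDistribution:
    """Summarize a sample of null normalized ranks (sample mean/SD + normal fit)."""
    vals = np.asarray(noninformative_results, dtype=float)
    if vals.size < min_values:
        raise ValueError(f"need at least {min_values} null values, got {vals.size}")
    return NullDistribution(vals, float(vals.mean()), float(vals.std(ddof=1)))


def significance_threshold(null: NullDistribution, k_sd: float = 2.4) -> float:
    """Decoding is significant below mean - k_sd * SD of the null
    (k_sd = 2.4 corresponds to p ~ 0.01 under a normal fit); reported to
    two decimals."""
    return round(null.mean - k_sd * null.sd, 2)


def mean_of_k_null(null_values: Sequence[float], k: int = 6, reps: int = 5000,
                   seed: int = 0) -> tuple[float, float]:
    """Null for a mean of k combined values: draw k values without
    replacement, average, repeat ``reps`` times; returns (mean, SD) of the
    resampled k-mean distribution."""
    vals = np.asarray(null_values, dtype=float)
    if k > vals.size:
        raise ValueError(f"k={k} exceeds the {vals.size} available null values")
    rng = np.random.default_rng(seed)
    means = np.array([vals[rng.choice(vals.size, size=k, replace=False)].mean()
                      for _ in range(reps)])
    return float(means.mean()), float(means.std(ddof=1))


def timepoint_curve(
    predictions_per_trial: Sequence[Mapping[str, np.ndarray]],
    correct_indices: Sequence[int],
    source: str,
    library: TrackLibrary,
    max_t: int | None = None,
    t_values: Sequence[int] | None = None,
) -> dict[int, float]:
    """Mean correct-track rank as a function of the number of leading TRs used.

    For each window length t, rankings are recomputed using only the first
    t TRs of both predicted and actual traces (resampling and
    standardization on the truncated window).  More time points should
    yield better (lower) correct-track ranks when decoding carries signal.
    """
    full = library.common_length
    if max_t is None:
        max_t = full
    if max_t > full:
        raise ValueError(f"max_t={max_t} exceeds the longest track ({full} TRs)")
    ts = list(t_values) if t_values is not None else list(range(2, max_t + 1))
    curve: dict[int, float] = {}
    for t in ts:
        ranks = [
            rank_tracks(preds, source, library, ci, max_trs=t).correct_rank
            for preds, ci in zip(predictions_per_trial, correct_indices)
        ]
        curve[t] = float(np.mean(ranks))
    return curve


@dataclass
class SimilarityResult:
    """Mean assigned rank of the most- vs least-similar foils."""

    mean_rank_most_similar: float
    mean_rank_least_similar: float
    t_stat: float
    p_value: float
    p_permutation: float


def track_similarity(library: TrackLibrary, source: str) -> np.ndarray:
    """Pairwise track dissimilarity for one source: SS_diff between the
    tracks' standardized actual variable vectors (smaller = more similar)."""
    L = library.common_length
    var_ids = [s.variable_id for s in library.variable_sets[0].by_source(source)]
    mats = []
    for vs in library.variable_sets:
        mats.append(np.concatenate([
            standardize(resample_linear(vs.get(source, vid).values, L)) for vid in var_ids
        ]))
    M = np.stack(mats)
    n = len(library)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = ss_diff(M[i], M[j])
    return out


def similarity_analysis(
    library: TrackLibrary,
    rankings: Sequence[RankStats],
    similarity_source: str,
    group_size: int = 5,
    n_permutations: int = 10000,
    seed: int = 0,
) -> SimilarityResult:
    """Do foils similar to the correct track get better (lower) ranks?

    For each trial, the ``group_size`` foils most and least similar to the
    correct track (similarity = SS_diff of actual traces for
    ``similarity_source``) are identified and their mean assigned ranks
    compared across trials by a paired t-test, backed by a sign-flip
    permutation test for small samples.
    """
    if len(library) < 2 * group_size + 1:
        raise ValueError(f"pool of {len(library)} too small for 2x{group_size} foil groups")
    dis = track_similarity(library, similarity_source)
    most, least = [], []
    for rs in rankings:
        ci = rs.correct_index
        foils = [k for k in range(len(library)) if k != ci]
        order = sorted(foils, key=lambda k: dis[ci, k])
        most.append(float(np.mean([rs.ranks[k] for k in order[:group_size]])))
        least.append(float(np.mean([rs.ranks[k] for k in order[-group_size:]])))
    most_a, least_a = np.asarray(most), np.asarray(least)
    diff = most_a - least_a
    t_stat, p_value = stats.ttest_rel(most_a, least_a)
    rng = np.random.default_rng(seed)
    obs = diff.mean()
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, diff.size))
    perm_means = (flips * diff).mean(axis=1)
    p_perm = float((np.abs(perm_means) >= abs(obs)).mean())
    return SimilarityResult(float(most_a.mean()), float(least_a.mean()),
                            float(t_stat), float(p_value), p_perm)


def identification_accuracy(rankings: Sequence[RankStats]) -> float:
    """Percent of trials whose correct track got rank 1 exactly."""
    if not rankings:
        raise ValueError("no rankings given")
    return 100.0 * float(np.mean([rs.correct_rank == 1.0 for rs in rankings]))


# ---------------------------------------------------------------------------
# figures


def plot_rank_curve(curve: Mapping[int, float], nr_tracks: int,
                    path: str | Path) -> None:
    """Mean correct-track rank vs number of leading TRs used, with the
    chance line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ts = sorted(curve)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ts, [curve[t] for t in ts], "o-", color="tab:blue")
    ax.axhline((nr_tracks + 1) / 2, ls=":", color="k", label="chance")
    ax.set_xlabel("time points (TRs) considered")
    ax.set_ylabel("mean correct-track rank")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_null_histogram(null: NullDistribution, path: str | Path,
                        k_sd: float = 2.4) -> None:
    """Null normalized-rank histogram with its normal fit and the
    significance threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(null.values, bins=15, density=True, color="0.7", edgecolor="0.4")
    grid = np.linspace(0, 1, 200)
    ax.plot(grid, stats.norm.pdf(grid, null.mean, max(null.sd, 1e-9)),
            color="tab:blue", label="normal fit")
    thr = significance_threshold(null, k_sd)
    ax.axvline(thr, color="tab:red", label=f"threshold {thr:.2f}")
    ax.set_xlabel("normalized correct-track rank")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# report


@dataclass
class EvaluationReport:
    """Summary of a full experiment: per-combination and combined results."""

    per_combination: dict[str, dict[str, float]]  # key -> {mean_rank, normalized, significant}
    null_mean: float
    null_sd: float
    threshold: float
    nr_tracks: int
    combined_mean_rank: float | None = None
    combined_normalized: float | None = None
    combined_identification_pct: float | None = None
    weights: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "null": {"mean": self.null_mean, "sd": self.null_sd, "threshold": self.threshold},
            "nr_tracks": self.nr_tracks,
            "per_combination": self.per_combination,
            "weights": self.weights,
            "combined": {
                "mean_rank": self.combined_mean_rank,
                "normalized_rank": self.combined_normalized,
                "identification_pct": self.combined_identification_pct,
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"candidate pool: {self.nr_tracks} tracks "
            f"(chance rank {(self.nr_tracks + 1) / 2:.1f}, normalized 0.5)",
            f"white-matter null: mean {self.null_mean:.3f}, sd {self.null_sd:.3f}; "
            f"significance threshold (mean - 2.4 sd): {self.threshold:.2f}",
            "",
            f"{'combination':<24}{'mean rank':>12}{'norm. rank':>12}{'signif.':>9}",
        ]
        for key in sorted(self.per_combination):
            row = self.per_combination[key]
            star = "*" if row["significant"] else ""
            lines.append(f"{key:<24}{row['mean_rank']:>12.2f}{row['normalized']:>12.3f}{star:>9}")
        if self.combined_mean_rank is not None:
            lines += [
                "",
                f"combined (weighted):    mean rank {self.combined_mean_rank:.2f}, "
                f"normalized {self.combined_normalized:.3f}, "
                f"identification {self.combined_identification_pct:.1f}%",
            ]
        return "\n".join(lines)
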