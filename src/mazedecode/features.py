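"""Behavioral and stimulus variables: six information sources, 73 variables.

Every variable is first computed at the frame rate of the maze software
(20 fps) and then binned to the temporal resolution of the fMRI images by
averaging the 60 frames falling into each TR of 3 s.  The six sources are

* ``quadrant``   — maze quadrant occupied per TR, expressed as 6 pairwise
                   variables (positions in the central band belong to no
                   quadrant and are excluded from classifier training);
* ``visibility`` — visible screen area of each of the 9 pictures, in [0, 1];
* ``motion``     — signed rotational motion per frame (degrees, turning
                   left positive, right negative, straight zero);
* ``reward``     — 1 at the TR when information about the next reward to
                   collect first appears, 0 otherwise;
* ``scene_rms``  — per-region standard deviation of scene luminance over a
                   5 x 5 grid whose middle square splits into 4, 28 regions;
* ``scene_temp`` — per-region sum of positive frame-to-frame luminance
                   increases over the same 28 regions.

6 + 9 + 1 + 1 + 28 + 28 = 73 variables, one binary classifier each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mazedecode.maze_world import Scene, Track

#: 20 fps x 3 s TR
FRAMES_PER_TR = 60

SOURCES = ("quadrant", "visibility", "motion", "reward", "scene_rms", "scene_temp")
SOURCE_COUNTS = {"quadrant": 6, "visibility": 9, "motion": 1, "reward": 1,
                 "scene_rms": 28, "scene_temp": 28}
QUADRANT_PAIRS = tuple(combinations((1, 2, 3, 4), 2))


def variable_roster() -> list[tuple[str, str]]:
    """Canonical ordering of the 73 (source, variable_id) pairs."""
    roster = [("quadrant", f"q{i}{j}") for i, j in QUADRANT_PAIRS]
    roster += [("visibility", f"pic{k + 1}") for k in range(9)]
    roster += [("motion", "rotation"), ("reward", "cue")]
    roster += [("scene_rms", f"sq{k:02d}") for k in range(28)]
    roster += [("scene_temp", f"sq{k:02d}") for k in range(28)]
    return roster


@dataclass
class VariableSeries:
    """One decoding variable: per-TR values (and the per-frame series they
    were binned from, where one exists).

    ``valid`` marks TRs eligible for classifier training; it is all-True
    except for quadrant-pair variables, where TRs spent in the unassigned
    middle band (or in neither quadrant of the pair) are masked out.
    """

    source: str
    variable_id: str
    values: np.ndarray
    frame_values: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)

    @property
    def n_trs(self) -> int:
        return len(self.values)


@dataclass
class VariableSet:
    """All 73 variables of one trial, on a common TR axis."""

    series: list[VariableSeries]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for s in self.series:
            counts[s.source] = counts.get(s.source, 0) + 1
        if counts != SOURCE_COUNTS:
            raise ValueError(f"variable census mismatch: {counts} != {SOURCE_COUNTS}")
        lengths = {s.n_trs for s in self.series}
        if len(lengths) != 1:
            raise ValueError(f"variables disagree on TR count: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def n_trs(self) -> int:
        return self.series[0].n_trs

    def by_source(self, source: str) -> list[VariableSeries]:
        return [s for s in self.series if s.source == source]

    def get(self, source: str, variable_id: str) -> VariableSeries:
        for s in self.series:
            if s.source == source and s.variable_id == variable_id:
                return s
        raise KeyError((source, variable_id))

    def to_frame(self, trial: int | str = 0) -> pd.DataFrame:
        """Long-format table (trial, source, variable_id, tr, value, valid)."""
        rows = []
        for s in self.series:
            for tr, (v, ok) in enumerate(zip(s.values, s.valid)):
                rows.append((trial, s.source, s.variable_id, tr, v, bool(ok)))
        return pd.DataFrame(rows, columns=["trial", "source", "variable_id", "tr", "value", "valid"])

    def to_tsv(self, path: str | Path, trial: int | str = 0) -> None:
        self.to_frame(trial).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariableSet":
        df = pd.read_csv(path, sep="\t")
        series = []
        for (source, vid), grp in df.groupby(["source", "variable_id"], sort=False):
            grp = grp.sort_values("tr")
            series.append(VariableSeries(source, str(vid), grp["value"].to_numpy(),
                                         valid=grp["valid"].to_numpy(dtype=bool)))
        order = {s: i for i, s in enumerate(SOURCES)}
        series.sort(key=lambda s: (order[s.source], s.variable_id))
        return cls(series)


# ---------------------------------------------------------------------------


def bin_to_tr(frame_series: Sequence[float] | np.ndarray, frames_per_tr: int = FRAMES_PER_TR) -> np.ndarray:
    """Average consecutive blocks of ``frames_per_tr`` frames into TR values.

    Bin t is the mean of frames [t*fpt, (t+1)*fpt); a final partial bin is
    averaged over the frames available, so the output length is
    ceil(n_frames / frames_per_tr).
    """
    x = np.asarray(frame_series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bin an empty series")
    if frames_per_tr < 1:
        raise ValueError("frames_per_tr must be >= 1")
    n_bins = -(-x.shape[0] // frames_per_tr)
    out = np.empty((n_bins,) + x.shape[1:], dtype=float)
    for t in range(n_bins):
        out[t] = x[t * frames_per_tr:(t + 1) * frames_per_tr].mean(axis=0)
    return out


@dataclass(frozen=True)
class QuadrantGeometry:
    """Four disjoint quadrant rectangles with an excluded middle band.

    Rectangles are half-open boxes in continuous tile coordinates
    ``(y_lo, y_hi, x_lo, x_hi)``; positions in none of them (the middle
    band) carry quadrant label 0.  The default splits the 20-tile interior
    into four 9 x 9 quadrants separated by a 2-tile central cross.
    """

    rects: tuple[tuple[float, float, float, float], ...] = (
        (1.0, 10.0, 1.0, 10.0),   # quadrant 1: north-west
        (1.0, 10.0, 12.0, 21.0),  # quadrant 2: north-east
        (12.0, 21.0, 1.0, 10.0),  # quadrant 3: south-west
        (12.0, 21.0, 12.0, 21.0), # quadrant 4: south-east
    )

    def __post_init__(self) -> None:
        for i, a in enumerate(self.rects):
            for b in self.rects[i + 1:]:
                if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                    raise ValueError("quadrant rectangles overlap")

    def label(self, x: float, y: float) -> int:
        for q, (y0, y1, x0, x1) in enumerate(self.rects, start=1):
            if y0 <= y < y1 and x0 <= x < x1:
                return q
        return 0


def quadrant_location(track: Track, geometry: QuadrantGeometry | None = None,
                      frames_per_tr: int = FRAMES_PER_TR) -> np.ndarray:
    """Per-TR quadrant label in {1..4}, 0 = unassigned middle band.

    The label is taken from the TR-mean (x, y) position.
    """
    geometry = geometry or QuadrantGeometry()
    mean_xy = bin_to_tr(track.poses[:, :2], frames_per_tr)
    return np.array([geometry.label(x, y) for x, y in mean_xy], dtype=int)


def quadrant_pair_series(labels: np.ndarray) -> list[VariableSeries]:
    """The 6 pairwise quadrant variables from a per-TR label sequence.

    For pair (i, j) the value is 1 in quadrant i, 0 in quadrant j and 0.5
    elsewhere; only TRs spent in i or j are marked training-eligible.
    """
    out = []
    for i, j in QUADRANT_PAIRS:
        values = np.where(labels == i, 1.0, np.where(labels == j, 0.0, 0.5))
        valid = (labels == i) | (labels == j)
        out.append(VariableSeries("quadrant", f"q{i}{j}", values, valid=valid))
    return out


def motion_path(track: Track, frames_per_tr: int = FRAMES_PER_TR) -> VariableSeries:
    """Signed rotational motion per frame (degrees; left positive), binned."""
    h = track.poses[:, 2]
    if len(h) < 2:
        raise ValueError("motion path needs at least 2 frames")
    d = np.diff(h)
    d = (d + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    frame_vals = np.concatenate([[0.0], d])
    return VariableSeries("motion", "rotation", bin_to_tr(frame_vals, frames_per_tr),
                          frame_values=frame_vals)


def reward_timing(track: Track, frames_per_tr: int = FRAMES_PER_TR) -> VariableSeries:
    """Binary per TR: 1 exactly at TRs containing a next-reward cue frame."""
    n_trs = -(-track.n_frames // frames_per_tr)
    vals = np.zeros(n_trs)
    for f in track.reward_events:
        vals[f // frames_per_tr] = 1.0
    frame_vals = np.zeros(track.n_frames)
    frame_vals[list(track.reward_events)] = 1.0
    return VariableSeries("reward", "cue", vals, frame_values=frame_vals)


def scene_grid(resolution: tuple[int, int]) -> np.ndarray:
    """Region index map for the 28-square scene summary.

    The frame is divided into a 5 x 5 grid of squares and the middle square
    is further divided into four smaller squares: 24 + 4 = 28 disjoint
    regions covering every pixel.  Returns an (H, W) int array with values
    0..27.  Remainder pixels from uneven division land in the last row or
    column of cells.
    """
    H, W = resolution
    if H < 10 or W < 10:
        raise ValueError("resolution must be at least 10x10 for a 5x5 grid")
    row_cell = np.minimum(np.arange(H) * 5 // H, 4)
    col_cell = np.minimum(np.arange(W) * 5 // W, 4)
    # force remainder pixels into the final cell of each axis
    row_cell = np.minimum(row_cell, 4)
    col_cell = np.minimum(col_cell, 4)
    cell = row_cell[:, None] * 5 + col_cell[None, :]
    labels = np.zeros((H, W), dtype=int)
    outer_ids = [i for i in range(25) if i != 12]
    for k, cid in enumerate(outer_ids):
        labels[cell == cid] = k
    # middle square (cell id 12) split into 2 x 2 sub-squares -> regions 24..27
    mid = cell == 12
    rows_mid = np.where(mid.any(axis=1))[0]
    cols_mid = np.where(mid.any(axis=0))[0]
    r_half = rows_mid[0] + (len(rows_mid) + 1) // 2
    c_half = cols_mid[0] + (len(cols_mid) + 1) // 2
    sub = (np.arange(H)[:, None] >= r_half) * 2 + (np.arange(W)[None, :] >= c_half)
    labels[mid] = (24 + sub)[mid]
    return labels


def _scene_feature_frames(scenes: Iterable[Scene], grid_map: np.ndarray | None = None):
    """Single pass over a scene stream: per-frame visibility (9), region RMS
    (28), and positive temporal change (28) without keeping frames around."""
    vis, rms, temp = [], [], []
    prev = None
    labels = grid_map
    counts = None
    for sc in scenes:
        if labels is None:
            labels = scene_grid(sc.luminance.shape)
        if counts is None:
            counts = np.bincount(labels.ravel(), minlength=28)
        lum = sc.luminance.ravel()
        lab = labels.ravel()
        n_pix = lum.size
        # picture visibility: mask-pixel share per picture
        vcount = np.bincount(sc.picture_mask.ravel(), minlength=10)[1:10]
        vis.append(vcount / n_pix)
        # population SD of luminance per region (two-pass for stability)
        mean = np.bincount(lab, weights=lum, minlength=28) / counts
        dev = lum - mean[lab]
        var = np.bincount(lab, weights=dev * dev, minlength=28) / counts
        rms.append(np.sqrt(var))
        # summed positive luminance increase per region
        if prev is None:
            temp.append(np.zeros(28))
        else:
            d = np.maximum(lum - prev, 0.0)
            temp.append(np.bincount(lab, weights=d, minlength=28))
        prev = lum
    return np.asarray(vis), np.asarray(rms), np.asarray(temp)


def picture_visibility(scenes: Iterable[Scene], frames_per_tr: int = FRAMES_PER_TR) -> list[VariableSeries]:
    """Visible-area score per picture and frame: the share of scene pixels
    showing the picture (0 = not visible, 1 = picture fills the scene)."""
    vis, _, _ = _scene_feature_frames(scenes)
    binned = bin_to_tr(vis, frames_per_tr)
    return [VariableSeries("visibility", f"pic{k+1}", binned[:, k], frame_values=vis[:, k])
            for k in range(9)]


def scene_rms(scenes: Iterable[Scene], frames_per_tr: int = FRAMES_PER_TR) -> list[VariableSeries]:
    """Per-region luminance standard deviation (population SD), binned."""
    _, rms, _ = _scene_feature_frames(scenes)
    binned = bin_to_tr(rms, frames_per_tr)
    return [VariableSeries("scene_rms", f"sq{k:02d}", binned[:, k], frame_values=rms[:, k])
            for k in range(28)]


def scene_temp(scenes: Iterable[Scene], frames_per_tr: int = FRAMES_PER_TR) -> list[VariableSeries]:
    """Per-region summed positive frame-to-frame luminance increase, binned."""
    _, _, temp = _scene_feature_frames(scenes)
    binned = bin_to_tr(temp, frames_per_tr)
    return [VariableSeries("scene_temp", f"sq{k:02d}", binned[:, k], frame_values=temp[:, k])
            for k in range(28)]


def build_variable_set(track: Track, scenes: Iterable[Scene],
                       geometry: QuadrantGeometry | None = None,
                       frames_per_tr: int = FRAMES_PER_TR) -> VariableSet:
    """Run every extractor and package the full 73-variable set.

    ``scenes`` is consumed in a single pass, so a lazy renderer generator
    (:func:`mazedecode.maze_world.render_track`) can be passed directly.
    """
    vis, rms, temp = _scene_feature_frames(scenes)
    n_frames = len(vis)
    if n_frames != track.n_frames:
        raise ValueError(f"scene count {n_frames} != track frames {track.n_frames}")
    labels = quadrant_location(track, geometry, frames_per_tr)
    series: list[VariableSeries] = []
    series += quadrant_pair_series(labels)
    vb = bin_to_tr(vis, frames_per_tr)
    series += [VariableSeries("visibility", f"pic{k+1}", vb[:, k], frame_values=vis[:, k])
               for k in range(9)]
    series.append(motion_path(track, frames_per_tr))
    series.append(reward_timing(track, frames_per_tr))
    rb = bin_to_tr(rms, frames_per_tr)
    series += [VariableSeries("scene_rms", f"sq{k:02d}", rb[:, k], frame_values=rms[:, k])
               for k in range(28)]
    tb = bin_to_tr(temp, frames_per_tr)
    series += [VariableSeries("scene_temp", f"sq{k:02d}", tb[:, k], frame_values=temp[:, k])
               for k in range(28)]
    return VariableSet(series)
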