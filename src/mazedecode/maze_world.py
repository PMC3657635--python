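"""Virtual maze environment: map, trials, routes, kinematics and rendering.

The environment is a 22 x 22 tile maze navigated in first person.  Walls and
corridors are fixed; seven *door pairs* vary between trials (exactly one door
of each pair is open on a given trial), nine pictures hang at fixed wall
positions, four fixed rewards must be collected in a per-trial order, and a
fifth bonus reward sits at one of four candidate sites on the outer corridor
and may be collected at any time.  Travel speed is one tile per 0.78 s and
scenes refresh at 20 frames per second.

Maze layout file format (plain text)
------------------------------------
22 lines of 22 characters (``#`` wall, ``.`` corridor), followed by
annotation lines::

    door <pair-id> (r,c) (r,c)      # the two mutually exclusive door cells
    picture <id> (r,c) <N|S|E|W> <texture-id>
    reward <id> (r,c)               # ids 1..4, collection order varies
    bonus (r,c) (r,c) (r,c) (r,c)   # candidate sites for reward 5
    start (r,c) <heading-deg>

Door cells are corridor cells; a closed door is impassable and is rendered
as a wall.  A picture's facing direction names the wall face it hangs on
(``N`` = the face toward smaller row indices), i.e. the side it is visible
from.  A 22 x 22 grayscale image (PNG/PGM, dark = wall) may replace the
character grid when paired with a separate annotation text file.

Coordinate conventions: 0-based ``(row, col)`` tile indices; continuous pose
``(x, y)`` in tile units with tile centers at half-integers (x along
columns, y along rows); heading in degrees, counter-clockwise positive,
0 deg = +x (east), 90 deg = north (decreasing row).
"""

from __future__ import annotations

import math
import re
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

FPS = 20
TILE_SECONDS = 0.78
#: tiles advanced per rendered frame when moving straight
SPEED_TILES_PER_FRAME = 1.0 / (TILE_SECONDS * FPS)
GRID_SIZE = 22

Cell = tuple[int, int]

_FACING_TO_VEC = {"N": (-1, 0), "S": (1, 0), "E": (0, 1), "W": (0, -1)}


@dataclass(frozen=True)
class Picture:
    """A picture hung on one face of a wall cell."""

    pic_id: int
    cell: Cell
    facing: str  # face it hangs on / is visible from
    texture_id: int


@dataclass
class MazeMap:
    """Static maze geometry: walls, door pairs, pictures and reward sites."""

    grid: np.ndarray  # (22, 22) bool, True = wall
    door_pairs: list[tuple[Cell, Cell]]
    pictures: list[Picture]
    fixed_rewards: dict[int, Cell]  # ids 1..4
    bonus_sites: list[Cell]
    start_cell: Cell = (1, 1)
    start_heading: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"maze grid must be {GRID_SIZE}x{GRID_SIZE}, got {self.grid.shape}")
        if not (~self.grid).any():
            raise ValueError("maze has no corridor cells")
        if len(self.door_pairs) != 7:
            raise ValueError(f"expected exactly 7 door pairs, got {len(self.door_pairs)}")
        if len(self.pictures) != 9:
            raise ValueError(f"expected exactly 9 pictures, got {len(self.pictures)}")
        if sorted(self.fixed_rewards) != [1, 2, 3, 4]:
            raise ValueError("fixed rewards must carry ids 1..4")
        if len(self.bonus_sites) != 4:
            raise ValueError(f"expected 4 bonus-reward candidate sites, got {len(self.bonus_sites)}")
        for pair in self.door_pairs:
            for cell in pair:
                if self.grid[cell]:
                    raise ValueError(f"door cell {cell} is not a corridor cell")
        for cell in list(self.fixed_rewards.values()) + self.bonus_sites + [self.start_cell]:
            if self.grid[cell]:
                raise ValueError(f"cell {cell} must lie on a corridor")
        for pic in self.pictures:
            if not self.grid[pic.cell]:
                raise ValueError(f"picture {pic.pic_id} cell {pic.cell} is not a wall cell")
            dr, dc = _FACING_TO_VEC[pic.facing]
            r, c = pic.cell[0] + dr, pic.cell[1] + dc
            if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE) or self.grid[r, c]:
                raise ValueError(
                    f"picture {pic.pic_id} faces {pic.facing} into a wall; it would never be visible"
                )

    def is_corridor(self, cell: Cell) -> bool:
        return not self.grid[cell]


@dataclass(frozen=True)
class TrialSpec:
    """Per-trial configuration: which doors are open, reward order, bonus site."""

    door_state: tuple[int, ...]  # per pair, index (0/1) of the OPEN door
    reward_order: tuple[int, int, int, int]
    bonus_site: Cell
    start_pose: tuple[Cell, float]
    rng_seed: int

    def __post_init__(self) -> None:
        if sorted(self.reward_order) != [1, 2, 3, 4]:
            raise ValueError("reward_order must be a permutation of 1..4")
        if any(s not in (0, 1) for s in self.door_state):
            raise ValueError("door_state entries must be 0 or 1")

    def closed_doors(self, maze: MazeMap) -> set[Cell]:
        return {pair[1 - open_idx] for pair, open_idx in zip(maze.door_pairs, self.door_state)}


@dataclass
class Track:
    """A navigated route: per-frame poses at 20 fps plus reward-cue events.

    ``poses`` is a float array of shape (n_frames, 3) holding (x, y,
    heading_deg).  ``reward_events`` are the frame indices at which the
    next-reward cue appears: frame 0 (the first cue is shown at trial start)
    and the frame each fixed reward is reached.
    """

    poses: np.ndarray
    reward_events: list[int]
    trial: TrialSpec
    fps: int = FPS

    @property
    def n_frames(self) -> int:
        return len(self.poses)

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV with columns frame, x, y, heading, event."""
        events = set(self.reward_events)
        with open(path, "w") as fh:
            fh.write("frame\tx\ty\theading\tevent\n")
            for i, (x, y, h) in enumerate(self.poses):
                fh.write(f"{i}\t{x:.5f}\t{y:.5f}\t{h:.3f}\t{int(i in events)}\n")


@dataclass
class Scene:
    """One rendered first-person frame.

    ``luminance`` is an (H, W) grayscale image in [0, 1]; ``picture_mask``
    an (H, W) integer image, 0 for background and k where the pixel shows
    picture k.
    """

    luminance: np.ndarray
    picture_mask: np.ndarray


# ---------------------------------------------------------------------------
# layout parsing

_CELL_RE = re.compile(r"\((\d+)\s*,\s*(\d+)\)")


def _parse_cells(text: str) -> list[Cell]:
    return [(int(r), int(c)) for r, c in _CELL_RE.findall(text)]


def load_maze(map_source: str | Path, annotations: str | Path | None = None) -> MazeMap:
    """Load a :class:`MazeMap` from a text layout (or image + annotations).

    ``map_source`` is a path to a layout text file as described in the
    module docstring, the layout text itself, or a path to a 22 x 22
    grayscale image (in which case ``annotations`` must point to a text
    file holding the annotation lines).
    """
    if annotations is not None:
        grid = _grid_from_image(Path(map_source))
        text = Path(annotations).read_text()
        return _build_maze(grid, text.splitlines())

    src = str(map_source)
    if "\n" not in src and Path(src).exists():
        src = Path(src).read_text()
    lines = src.splitlines()
    grid_lines = [ln for ln in lines if set(ln.strip()) <= {"#", "."} and ln.strip()]
    if len(grid_lines) != GRID_SIZE or any(len(ln.strip()) != GRID_SIZE for ln in grid_lines):
        raise ValueError(
            f"layout must contain {GRID_SIZE} grid lines of {GRID_SIZE} '#'/'.' characters"
        )
    grid = np.array([[ch == "#" for ch in ln.strip()] for ln in grid_lines], dtype=bool)
    return _build_maze(grid, lines)


def _grid_from_image(path: Path) -> np.ndarray:
    from PIL import Image

    img = np.asarray(Image.open(path).convert("L"), dtype=float)
    if img.shape != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"maze image must be {GRID_SIZE}x{GRID_SIZE} pixels, got {img.shape}")
    return img < 128  # dark = wall


def _build_maze(grid: np.ndarray, lines: Iterable[str]) -> MazeMap:
    door_pairs: list[tuple[Cell, Cell]] = []
    pictures: list[Picture] = []
    rewards: dict[int, Cell] = {}
    bonus: list[Cell] = []
    start_cell: Cell = (1, 1)
    start_heading = 0.0
    for raw in lines:
        line = raw.split("#", 1)[0].strip() if not set(raw.strip()) <= {"#", "."} else ""
        if not line:
            continue
        tok = line.split()
        kind = tok[0].lower()
        if kind == "door":
            cells = _parse_cells(line)
            if len(cells) != 2:
                raise ValueError(f"door line needs two cells: {raw!r}")
            door_pairs.append((cells[0], cells[1]))
        elif kind == "picture":
            cells = _parse_cells(line)
            facing = tok[-2].upper()
            if facing not in _FACING_TO_VEC:
                raise ValueError(f"bad picture facing in {raw!r}")
            pictures.append(Picture(int(tok[1]), cells[0], facing, int(tok[-1])))
        elif kind == "reward":
            rewards[int(tok[1])] = _parse_cells(line)[0]
        elif kind == "bonus":
            bonus = _parse_cells(line)
        elif kind == "start":
            start_cell = _parse_cells(line)[0]
            start_heading = float(tok[-1])
        else:
            raise ValueError(f"unrecognised annotation line: {raw!r}")
    return MazeMap(grid, door_pairs, pictures, rewards, bonus, start_cell, start_heading)


def default_maze() -> MazeMap:
    """The bundled default maze layout."""
    text = resources.files("mazedecode").joinpath("data/default_maze.txt").read_text()
    return load_maze(text)


# ---------------------------------------------------------------------------
# trials and routes


def sample_trial(maze: MazeMap, seed: int) -> TrialSpec:
    """Draw a uniformly random trial configuration, reproducible per seed."""
    rng = np.random.default_rng(seed)
    door_state = tuple(int(v) for v in rng.integers(0, 2, size=len(maze.door_pairs)))
    reward_order = tuple(int(i) for i in rng.permutation([1, 2, 3, 4]))
    bonus_site = maze.bonus_sites[int(rng.integers(len(maze.bonus_sites)))]
    return TrialSpec(
        door_state=door_state,
        reward_order=reward_order,  # type: ignore[arg-type]
        bonus_site=bonus_site,
        start_pose=(maze.start_cell, maze.start_heading),
        rng_seed=int(seed),
    )


def _neighbors(maze: MazeMap, cell: Cell, closed: set[Cell]) -> Iterable[Cell]:
    r, c = cell
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = (r + dr, c + dc)
        if 0 <= nb[0] < GRID_SIZE and 0 <= nb[1] < GRID_SIZE:
            if not maze.grid[nb] and nb not in closed:
                yield nb


def _bfs_path(maze: MazeMap, src: Cell, dst: Cell, closed: set[Cell]) -> list[Cell] | None:
    if src == dst:
        return [src]
    prev: dict[Cell, Cell] = {src: src}
    queue = deque([src])
    while queue:
        cur = queue.popleft()
        for nb in _neighbors(maze, cur, closed):
            if nb not in prev:
                prev[nb] = cur
                if nb == dst:
                    path = [nb]
                    while path[-1] != src:
                        path.append(prev[path[-1]])
                    return path[::-1]
                queue.append(nb)
    return None


def plan_route(
    maze: MazeMap,
    trial: TrialSpec,
    detour_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Cell]:
    """Plan a tile path visiting the fixed rewards in order plus the bonus.

    Stands in for the human navigator: breadth-first shortest paths between
    consecutive goals, with closed doors impassable.  The bonus reward is
    inserted between the pair of consecutive goals (or after the last) where
    it adds the least extra length — the navigator is free to collect it at
    any time.  With ``detour_prob`` > 0, each leg is, with that probability,
    routed through a random intermediate corridor cell, emulating suboptimal
    human routes so that pools of candidate tracks are not degenerate.
    """
    closed = trial.closed_doors(maze)
    goals: list[Cell] = [trial.start_pose[0]] + [maze.fixed_rewards[i] for i in trial.reward_order]

    def dist(a: Cell, b: Cell) -> int:
        p = _bfs_path(maze, a, b, closed)
        if p is None:
            raise RuntimeError(
                f"reward at {b} unreachable from {a} with closed doors {sorted(closed)}"
            )
        return len(p) - 1

    # insert the bonus reward where it costs the least detour
    bonus = trial.bonus_site
    best_pos, best_added = len(goals) - 1, None
    for i in range(len(goals) - 1):
        added = dist(goals[i], bonus) + dist(bonus, goals[i + 1]) - dist(goals[i], goals[i + 1])
        if best_added is None or added < best_added:
            best_pos, best_added = i, added
    tail_added = dist(goals[-1], bonus)
    if best_added is None or tail_added < best_added:
        goals.append(bonus)
    else:
        goals.insert(best_pos + 1, bonus)

    if detour_prob > 0 and rng is None:
        rng = np.random.default_rng(trial.rng_seed)
    # detour waypoints must be reachable: some door configurations wall off
    # whole inner regions, which is legitimate maze behavior
    reachable: set[Cell] = {goals[0]}
    frontier = deque([goals[0]])
    while frontier:
        for nb in _neighbors(maze, frontier.popleft(), closed):
            if nb not in reachable:
                reachable.add(nb)
                frontier.append(nb)
    corridor_cells = sorted(reachable)

    path: list[Cell] = [goals[0]]
    for a, b in zip(goals[:-1], goals[1:]):
        waypoints = [b]
        if detour_prob > 0 and rng is not None and rng.random() < detour_prob:
            via = corridor_cells[int(rng.integers(len(corridor_cells)))]
            waypoints = [via, b]
        for wp in waypoints:
            leg = _bfs_path(maze, path[-1], wp, closed)
            if leg is None:
                raise RuntimeError(
                    f"goal {wp} unreachable from {path[-1]} with closed doors {sorted(closed)}"
                )
            path.extend(leg[1:])
    return path


# ---------------------------------------------------------------------------
# kinematics


def _heading_for_step(a: Cell, b: Cell) -> float:
    dr, dc = b[0] - a[0], b[1] - a[1]
    # 0 = east (+col); north (-row) = +90 (counter-clockwise positive)
    return math.degrees(math.atan2(-dr, dc)) % 360.0


def _ang_diff(target: float, current: float) -> float:
    """Signed smallest rotation from current to target, in (-180, 180]."""
    d = (target - current) % 360.0
    return d - 360.0 if d > 180.0 else d


def simulate_track(
    path: Sequence[Cell],
    trial: TrialSpec,
    turn_rate: float = 6.0,
    maze: MazeMap | None = None,
) -> Track:
    """Convert a tile path into a per-frame pose sequence.

    The navigator alternates straight segments (1 tile per 0.78 s, i.e.
    ``SPEED_TILES_PER_FRAME`` per frame) with in-place turns at ``turn_rate``
    degrees per frame — turning and advancing are separate button presses, so
    forward speed is zero while turning.  Reward-cue events are recorded at
    frame 0 and at the frame each fixed reward cell is reached (information
    about the next reward appears when the previous one is collected).
    """
    if turn_rate <= 0:
        raise ValueError("turn_rate must be positive")
    if len(path) == 0:
        raise ValueError("empty path")

    # the reward sequence the navigator is cued through; a cell crossed out
    # of turn does not collect its reward
    expected: list[Cell] = []
    if maze is not None:
        expected = [maze.fixed_rewards[rid] for rid in trial.reward_order]

    def center(cell: Cell) -> tuple[float, float]:
        return (cell[1] + 0.5, cell[0] + 0.5)

    # merge the tile path into maximal straight segments so that forward
    # motion is continuous (no per-tile rounding of the 15.6 frames/tile)
    segments: list[tuple[Cell, list[Cell]]] = []
    last_step: tuple[int, int] | None = None
    for prev, cur in zip(path[:-1], path[1:]):
        step = (cur[0] - prev[0], cur[1] - prev[1])
        if step == last_step:
            segments[-1][1].append(cur)
        else:
            segments.append((prev, [cur]))
            last_step = step

    heading = trial.start_pose[1]
    x, y = center(path[0])
    poses: list[tuple[float, float, float]] = [(x, y, heading)]
    reward_events: list[int] = [0]
    next_reward = 0

    for seg_start, seg_cells in segments:
        target_h = _heading_for_step(seg_start, seg_cells[0])
        diff = _ang_diff(target_h, heading)
        n_turn = math.ceil(abs(diff) / turn_rate - 1e-9)
        for k in range(n_turn):
            step_deg = math.copysign(min(turn_rate, abs(diff) - k * turn_rate), diff)
            heading = (heading + step_deg) % 360.0
            poses.append((x, y, heading))
        heading = target_h % 360.0
        # continuous advance along the whole straight segment
        tx, ty = center(seg_cells[-1])
        dist = math.hypot(tx - x, ty - y)
        ux, uy = (tx - x) / dist, (ty - y) / dist
        n_move = math.ceil(dist / SPEED_TILES_PER_FRAME - 1e-9)
        seg_frame0 = len(poses) - 1
        for k in range(1, n_move + 1):
            d = min(k * SPEED_TILES_PER_FRAME, dist)
            poses.append((x + ux * d, y + uy * d, heading))
        # reward cues fire at the frame the cued reward's tile center is reached
        for cell in seg_cells:
            if next_reward < len(expected) and cell == expected[next_reward]:
                d_cell = math.hypot(center(cell)[0] - x, center(cell)[1] - y)
                k_evt = max(1, math.ceil(d_cell / SPEED_TILES_PER_FRAME - 1e-9))
                reward_events.append(seg_frame0 + k_evt)
                next_reward += 1
        x, y = tx, ty

    return Track(np.asarray(poses, dtype=float), reward_events, trial)


# ---------------------------------------------------------------------------
# ray-cast renderer

SKY_LUMINANCE = 0.12
FLOOR_LUMINANCE = 0.33
_PIC_U = (0.08, 0.92)  # picture extent along the wall face
_PIC_V = (0.10, 0.90)  # picture extent up the wall


def _brick_texture(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Procedural brick pattern: per-brick luminance jitter + mortar lines."""
    bv = v * 4.0
    row = np.floor(bv)
    bu = u * 3.0 + 0.5 * (row % 2)
    col = np.floor(bu)
    jitter = 0.12 * (((row * 7 + col * 13) % 5) / 4.0 - 0.5)
    lum = 0.66 + jitter
    mortar = ((bv - row) < 0.12) | ((bu - col) < 0.08)
    return np.where(mortar, 0.42, lum)


def _picture_texture(u: np.ndarray, v: np.ndarray, texture_id: int) -> np.ndarray:
    ph = 0.9 * texture_id
    lum = 0.5 + 0.28 * np.sin(2 * np.pi * (texture_id * u + v) + ph) * np.cos(
        2 * np.pi * (u - texture_id * 0.3 * v)
    )
    return np.clip(lum, 0.05, 0.95)


def render_frame(
    maze: MazeMap,
    pose: tuple[float, float, float],
    resolution: tuple[int, int] = (150, 200),
    fov: float = 60.0,
    trial: TrialSpec | None = None,
) -> Scene:
    """Ray-cast one first-person frame from ``pose`` = (x, y, heading_deg).

    One ray per screen column (grid DDA); closed doors of ``trial`` are
    rendered as walls, open doors as passable gaps.  Pictures appear as
    textured quads on their wall face and are flagged per pixel in the
    scene's ``picture_mask`` (hence automatically occlusion-aware).
    Deterministic: same inputs, identical images.
    """
    H, W = resolution
    x, y, heading = float(pose[0]), float(pose[1]), float(pose[2])
    cell = (int(math.floor(y)), int(math.floor(x)))
    if not (0 <= cell[0] < GRID_SIZE and 0 <= cell[1] < GRID_SIZE) or maze.grid[cell]:
        raise ValueError(f"pose {pose} lies inside a wall cell {cell}")

    solid = maze.grid.copy()
    if trial is not None:
        for dc_ in trial.closed_doors(maze):
            solid[dc_] = True

    # per-face picture lookup: (cell, facing) -> (pic_id, texture_id)
    pics = {(p.cell, p.facing): (p.pic_id, p.texture_id) for p in maze.pictures}

    col_angles = np.deg2rad(heading + fov / 2 - fov * (np.arange(W) + 0.5) / W)
    dx = np.cos(col_angles)
    dy = -np.sin(col_angles)  # heading 90 = north = decreasing row/y

    # vectorised DDA grid traversal
    eps = 1e-12
    ix = np.full(W, cell[1], dtype=int)
    iy = np.full(W, cell[0], dtype=int)
    ddx = 1.0 / np.maximum(np.abs(dx), eps)
    ddy = 1.0 / np.maximum(np.abs(dy), eps)
    step_x = np.where(dx >= 0, 1, -1)
    step_y = np.where(dy >= 0, 1, -1)
    side_x = np.where(dx >= 0, (ix + 1) - x, x - ix) * ddx
    side_y = np.where(dy >= 0, (iy + 1) - y, y - iy) * ddy

    hit = np.zeros(W, dtype=bool)
    hit_side = np.zeros(W, dtype=np.int8)  # 0: crossed a col boundary, 1: row boundary
    t_hit = np.full(W, np.inf)
    for _ in range(2 * GRID_SIZE):
        act = ~hit
        if not act.any():
            break
        go_x = act & (side_x <= side_y)
        go_y = act & ~go_x
        ix[go_x] += step_x[go_x]
        iy[go_y] += step_y[go_y]
        t_new = np.where(go_x, side_x, side_y)
        side_x[go_x] += ddx[go_x]
        side_y[go_y] += ddy[go_y]
        inside = (ix >= 0) & (ix < GRID_SIZE) & (iy >= 0) & (iy < GRID_SIZE)
        oob = act & ~inside
        hit[oob] = True  # border walls guarantee this rarely triggers
        t_hit[oob] = t_new[oob]
        newly = act & inside & solid[np.clip(iy, 0, GRID_SIZE - 1), np.clip(ix, 0, GRID_SIZE - 1)]
        hit[newly] = True
        hit_side[go_x & newly] = 0
        hit_side[go_y & newly] = 1
        t_hit[newly] = t_new[newly]

    t_hit = np.where(np.isfinite(t_hit), t_hit, 2 * GRID_SIZE)
    hx = x + dx * t_hit
    hy = y + dy * t_hit
    u_face = np.where(hit_side == 0, hy - np.floor(hy), hx - np.floor(hx))

    # which face was struck (the face the ray entered through)
    face = np.where(
        hit_side == 0,
        np.where(step_x > 0, 0, 1),  # moving +x strikes the west face, code 0; east 1
        np.where(step_y > 0, 2, 3),  # moving +y (south) strikes the north face 2; south 3
    )
    face_name = np.array(["W", "E", "N", "S"])

    pic_id_col = np.zeros(W, dtype=int)
    pic_tex_col = np.zeros(W, dtype=int)
    for w in range(W):
        key = ((int(iy[w]), int(ix[w])), face_name[face[w]])
        if key in pics and _PIC_U[0] <= u_face[w] <= _PIC_U[1]:
            pic_id_col[w], pic_tex_col[w] = pics[key]

    perp = np.maximum(t_hit * np.cos(col_angles - np.deg2rad(heading)), 1e-6)
    half_h = (H / 2.0) / perp
    rows = np.arange(H)[:, None]
    top = H / 2.0 - half_h[None, :]
    bottom = H / 2.0 + half_h[None, :]
    on_wall = (rows >= top) & (rows < bottom)
    v = np.clip((rows - top) / np.maximum(bottom - top, 1e-9), 0.0, 1.0 - 1e-9)

    u2 = np.broadcast_to(u_face[None, :], (H, W))
    lum = _brick_texture(u2, v)
    # classic two-tone side shading for depth cueing
    lum = lum * np.where(hit_side[None, :] == 0, 1.0, 0.82)

    picture_mask = np.zeros((H, W), dtype=int)
    has_pic = pic_id_col[None, :] > 0
    u_rel = (u2 - _PIC_U[0]) / (_PIC_U[1] - _PIC_U[0])
    v_rel = (v - _PIC_V[0]) / (_PIC_V[1] - _PIC_V[0])
    in_pic = has_pic & on_wall & (v >= _PIC_V[0]) & (v < _PIC_V[1])
    if in_pic.any():
        tex = np.zeros((H, W))
        for tid in np.unique(pic_tex_col[pic_id_col > 0]):
            sel = in_pic & (pic_tex_col[None, :] == tid)
            tex[sel] = _picture_texture(np.clip(u_rel, 0, 1), np.clip(v_rel, 0, 1), int(tid))[sel]
        lum = np.where(in_pic, tex, lum)
        picture_mask = np.where(in_pic, pic_id_col[None, :], 0)

    image = np.where(on_wall, lum, np.where(rows < H / 2.0, SKY_LUMINANCE, FLOOR_LUMINANCE))
    return Scene(np.clip(image, 0.0, 1.0), picture_mask)


def render_track(
    maze: MazeMap,
    track: Track,
    resolution: tuple[int, int] = (150, 200),
    fov: float = 60.0,
) -> Iterable[Scene]:
    """Lazily render every frame of a track (memory-friendly generator)."""
    for pose in track.poses:
        yield render_frame(maze, tuple(pose), resolution, fov, trial=track.trial)
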