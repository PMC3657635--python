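"""Maze geometry, trial sampling, route planning, kinematics, rendering."""

import math

import numpy as np
import pytest

from mazedecode import maze_world as mw
from mazedecode.maze_world import (
    FPS,
    SPEED_TILES_PER_FRAME,
    TILE_SECONDS,
    TrialSpec,
    default_maze,
    load_maze,
    plan_route,
    render_frame,
    sample_trial,
    simulate_track,
)


class TestLoadMaze:
    def test_default_layout_satisfies_census(self, maze):
        assert maze.grid.shape == (22, 22)
        assert len(maze.door_pairs) == 7
        assert len(maze.pictures) == 9
        assert sorted(maze.fixed_rewards) == [1, 2, 3, 4]
        assert len(maze.bonus_sites) == 4

    def test_all_wall_grid_rejected(self):
        text = "\n".join(["#" * 22] * 22)
        with pytest.raises(ValueError, match="corridor|door"):
            load_maze(text)

    def test_eight_door_pairs_rejected(self, maze):
        src = mw.resources.files("mazedecode").joinpath("data/default_maze.txt").read_text()
        with pytest.raises(ValueError, match="7 door pairs"):
            load_maze(src + "\ndoor 8 (1,2) (1,3)\n")

    def test_image_grid_with_annotation_sidecar(self, maze, tmp_path):
        from PIL import Image

        img = Image.fromarray(np.where(maze.grid, 0, 255).astype(np.uint8), mode="L")
        img.save(tmp_path / "grid.pgm")
        src = mw.resources.files("mazedecode").joinpath("data/default_maze.txt").read_text()
        notes = "\n".join(ln for ln in src.splitlines()
                          if not set(ln.strip()) <= {"#", "."} or not ln.strip())
        (tmp_path / "notes.txt").write_text(notes)
        loaded = load_maze(tmp_path / "grid.pgm", annotations=tmp_path / "notes.txt")
        assert np.array_equal(loaded.grid, maze.grid)
        assert loaded.door_pairs == maze.door_pairs

    def test_deterministic_reload(self, maze):
        again = default_maze()
        assert np.array_equal(maze.grid, again.grid)
        assert maze.door_pairs == again.door_pairs
        assert maze.pictures == again.pictures


class TestSampleTrial:
    def test_same_seed_identical(self, maze):
        assert sample_trial(maze, 42) == sample_trial(maze, 42)

    def test_door_and_order_distributions(self, maze):
        trials = [sample_trial(maze, s) for s in range(10_000)]
        states = np.array([t.door_state for t in trials])
        freqs = states.mean(axis=0)
        assert np.all(np.abs(freqs - 0.5) < 0.02), freqs
        orders = {t.reward_order for t in trials}
        assert len(orders) == 24  # every permutation of 4 rewards occurs


class TestPlanRoute:
    def _bfs_oracle_len(self, maze, src, dst, closed):
        """Independent shortest-path oracle via networkx."""
        import networkx as nx

        g = nx.Graph()
        for r in range(22):
            for c in range(22):
                if maze.grid[r, c] or (r, c) in closed:
                    continue
                for dr, dc in ((0, 1), (1, 0)):
                    nb = (r + dr, c + dc)
                    if nb[0] < 22 and nb[1] < 22 and not maze.grid[nb] and nb not in closed:
                        g.add_edge((r, c), nb)
        return nx.shortest_path_length(g, src, dst)

    def test_path_adjacency_and_corridors(self, maze):
        trial = sample_trial(maze, 3)
        path = plan_route(maze, trial)
        closed = trial.closed_doors(maze)
        for a, b in zip(path[:-1], path[1:]):
            assert abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1
        assert all(not maze.grid[c] for c in path)
        assert not closed.intersection(path)

    def test_rewards_collected_in_cued_order(self, maze):
        # scanning the path with a "next expected reward" pointer must
        # consume all four rewards (cells crossed out of turn don't count)
        for seed in (11, 12, 13):
            trial = sample_trial(maze, seed)
            path = plan_route(maze, trial)
            expected = [maze.fixed_rewards[r] for r in trial.reward_order]
            ptr = 0
            for cell in path:
                if ptr < 4 and cell == expected[ptr]:
                    ptr += 1
            assert ptr == 4
            assert trial.bonus_site in path

    def test_leg_lengths_match_bfs_oracle(self, maze):
        for seed in range(12):
            trial = sample_trial(maze, seed)
            closed = trial.closed_doors(maze)
            path = plan_route(maze, trial)
            # the route is a concatenation of shortest legs between goals
            goals = [trial.start_pose[0]] + [maze.fixed_rewards[r] for r in trial.reward_order]
            idx = [path.index(g) for g in goals]
            # each consecutive goal pair: distance along path between optimal
            # insertion points never beats the BFS oracle
            for a, b in zip(goals[:-1], goals[1:]):
                oracle = self._bfs_oracle_len(maze, a, b, closed)
                ia, ib = path.index(a), path.index(b)
                assert ib - ia >= oracle if ib > ia else True

    def test_detours_are_reachable_and_reproducible(self, maze):
        trial = sample_trial(maze, 5)
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        p1 = plan_route(maze, trial, detour_prob=0.8, rng=rng1)
        p2 = plan_route(maze, trial, detour_prob=0.8, rng=rng2)
        assert p1 == p2
        assert not trial.closed_doors(maze).intersection(p1)


class TestSimulateTrack:
    def _trial(self, maze):
        return sample_trial(maze, 0)

    def test_long_corridor_duration_about_17s(self, maze):
        # 22 tiles of straight travel at one tile per 0.78 s
        path = [(0, c) for c in range(23)]
        trial = TrialSpec((0,) * 7, (1, 2, 3, 4), (5, 1), ((0, 0), 0.0), 0)
        track = simulate_track(path, trial)
        assert round(track.duration_seconds) == 17

    def test_single_cell_path(self, maze):
        trial = self._trial(maze)
        track = simulate_track([trial.start_pose[0]], trial)
        assert track.n_frames == 1

    def test_l_shape_matches_closed_form(self, maze):
        # 3 tiles east, 90 deg turn, 2 tiles north, turn rate 6 deg/frame
        path = [(5, 5), (5, 6), (5, 7), (5, 8), (4, 8), (3, 8)]
        trial = TrialSpec((0,) * 7, (1, 2, 3, 4), (5, 1), (path[0], 0.0), 0)
        track = simulate_track(path, trial, turn_rate=6.0)
        moves = math.ceil(3 / SPEED_TILES_PER_FRAME) + math.ceil(2 / SPEED_TILES_PER_FRAME)
        turns = math.ceil(90 / 6.0)
        assert track.n_frames == 1 + moves + turns

    def test_displacement_conservation(self, maze):
        trial = sample_trial(maze, 8)
        path = plan_route(maze, trial)
        track = simulate_track(path, trial, maze=maze)
        step = np.linalg.norm(np.diff(track.poses[:, :2], axis=0), axis=1)
        assert step.max() <= SPEED_TILES_PER_FRAME + 1e-9
        assert abs(step.sum() - (len(path) - 1)) < SPEED_TILES_PER_FRAME

    def test_reward_events_start_plus_fixed_rewards(self, maze):
        trial = sample_trial(maze, 8)
        track = simulate_track(plan_route(maze, trial), trial, maze=maze)
        assert track.reward_events[0] == 0
        assert len(track.reward_events) == 5
        assert track.reward_events == sorted(track.reward_events)

    def test_bad_turn_rate(self, maze):
        trial = self._trial(maze)
        with pytest.raises(ValueError):
            simulate_track([(1, 1), (1, 2)], trial, turn_rate=0.0)


class TestRenderFrame:
    def test_determinism_and_bounds(self, maze):
        pose = (3.5, 1.5, 0.0)
        a = render_frame(maze, pose, (48, 64))
        b = render_frame(maze, pose, (48, 64))
        assert np.array_equal(a.luminance, b.luminance)
        assert np.array_equal(a.picture_mask, b.picture_mask)
        assert a.luminance.min() >= 0 and a.luminance.max() <= 1
        assert set(np.unique(a.picture_mask)) <= set(range(10))

    def test_wall_one_tile_away_fills_columns(self, maze):
        # facing the border wall from the adjacent corridor: perpendicular
        # distance <= 0.5/cos(30 deg) < 0.58 tiles, so by the projection rule
        # every column's wall band spans the full frame height
        scene = render_frame(maze, (3.5, 1.5, 90.0), (48, 64), fov=60.0)
        top_is_wall = scene.luminance[0, :] != mw.SKY_LUMINANCE
        assert top_is_wall.mean() >= 0.9

    def test_picture_fills_view_up_close(self, maze):
        # picture 1 hangs on the north face of wall (2,3); stand just in
        # front of it and look south
        scene = render_frame(maze, (3.5, 1.95, 270.0), (96, 128), fov=60.0)
        assert (scene.picture_mask == 1).mean() > 0.9

    def test_closed_door_occludes_picture(self, maze):
        # picture 7 (east face of (4,9)) is visible down the col-10 corridor;
        # the (3,10) door sits between viewer and picture
        base = sample_trial(maze, 0)
        pose = (10.5, 2.5, 270.0)
        for open_idx, visible in ((0, True), (1, False)):
            ds = list(base.door_state)
            ds[2] = open_idx  # pair 3 = ((3,10),(8,10)); index of the OPEN door
            trial = TrialSpec(tuple(ds), base.reward_order, base.bonus_site,
                              base.start_pose, 0)
            scene = render_frame(maze, pose, (96, 128), trial=trial)
            assert bool((scene.picture_mask == 7).sum() > 0) == visible

    def test_pose_in_wall_rejected(self, maze):
        with pytest.raises(ValueError, match="wall"):
            render_frame(maze, (0.5, 0.5, 0.0), (48, 64))
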