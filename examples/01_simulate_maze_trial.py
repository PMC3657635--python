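"""Simulate one navigation trial: maze -> trial -> route -> kinematics.

Loads the bundled 22x22 maze, draws a random trial configuration (door
states, reward order, bonus site), plans a route visiting the rewards in
order, and converts it into a 20-fps pose sequence at one tile per 0.78 s.
"""

from mazedecode import default_maze, plan_route, render_frame, sample_trial, simulate_track

maze = default_maze()
trial = sample_trial(maze, seed=7)
print(f"open doors (index per pair): {trial.door_state}")
print(f"reward collection order:     {trial.reward_order}, bonus at {trial.bonus_site}")

path = plan_route(maze, trial)
track = simulate_track(path, trial, maze=maze)
print(f"route: {len(path)} tiles, duration {track.duration_seconds:.1f} s "
      f"({track.n_frames} frames at 20 fps)")
print(f"reward cues appear at frames {track.reward_events} "
      "(trial start counts as the first cue)")

scene = render_frame(maze, tuple(track.poses[300]), resolution=(96, 128), trial=trial)
visible = sorted(set(scene.picture_mask.ravel()) - {0})
print(f"frame 300 first-person view: luminance in "
      f"[{scene.luminance.min():.2f}, {scene.luminance.max():.2f}], "
      f"pictures visible: {visible or 'none'}")
# Duration must fall in the plausible per-trial range and each reward cue
# marks the moment the navigator learns the next goal.
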