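"""Extract the 73 decoding variables from one simulated trial.

The six information sources (quadrant pairs, picture visibility, rotational
motion, reward timing, and the 28-square spatial and temporal scene
summaries) are computed at 20 fps and averaged into 3-s TR bins.
"""

from mazedecode import (
    build_variable_set,
    default_maze,
    plan_route,
    render_track,
    sample_trial,
    simulate_track,
)

maze = default_maze()
trial = sample_trial(maze, seed=3)
track = simulate_track(plan_route(maze, trial), trial, maze=maze)
scenes = render_track(maze, track, resolution=(48, 64))  # lazy generator
variables = build_variable_set(track, scenes)

print(f"trial of {track.duration_seconds:.0f} s -> {variables.n_trs} TRs, "
      f"{len(variables)} variables")
for source in ("quadrant", "visibility", "motion", "reward", "scene_rms", "scene_temp"):
    n = len(variables.by_source(source))
    print(f"  {source:<11} {n:2d} variable(s)")

motion = variables.get("motion", "rotation")
print(f"motion (deg/frame, left positive), first 8 TRs: "
      f"{[round(float(v), 2) for v in motion.values[:8]]}")
reward = variables.get("reward", "cue")
print(f"reward-cue TRs: {[t for t, v in enumerate(reward.values) if v == 1]}")
# Each variable becomes one binary classifier per region of interest.
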