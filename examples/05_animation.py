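"""Render a whole simulation as an animation.

One SVG frame per displayed time point, in time order, plus an optional
GIF; the per-frame duration is 1000 / speed milliseconds.  The related
dwell-time rule for interactive scrubbing is exposed as a pure function:
a time point selected for less than 5*m ms (m = maximal number of
structures per time point) emits no frame.
"""

from pathlib import Path

from cofoldviz import RenderConfig, generate_fixture, min_dwell_time, write_animation

traj = generate_fixture("late-refold", seed=1, n_timepoints=10, final_length=24)
cfg = RenderConfig(min_occupancy=0.01, speed=4.0)

outdir = Path("animation_frames")
paths = write_animation(traj, cfg, outdir=outdir, gif_path=outdir / "animation.gif")
print(f"wrote {len(paths)} SVG frames and a GIF to {outdir}/")
print(f"frame duration: {1000 / cfg.speed:.0f} ms (speed = {cfg.speed} frames/s)")

m = max(len(traj.records_at(t)) for t in traj.times)
print(f"max structures per time point m = {m}; "
      f"minimum dwell time for a frame: {min_dwell_time(m):.0f} ms")
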