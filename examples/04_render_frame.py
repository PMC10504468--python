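"""Render one composite figure to SVG.

The frame shows the structure ensemble at the chosen time point as a
treemap (tile area proportional to occupancy, occupancy decreasing left
to right, nucleotides colored by their pair's imaginary center) above
the whole-simulation overview strip with the black end-of-transcription
marker at 75% of the axis width and a red cursor at the current time.
"""

from pathlib import Path

from cofoldviz import RenderConfig, generate_fixture, render_frame, slice_at_time

traj = generate_fixture("helix-competition", seed=1, n_timepoints=12, final_length=30)
cfg = RenderConfig(min_occupancy=0.01)

t = 2.0  # mid-transcription, while the two helices compete
svg = render_frame(traj, t, cfg)
out = Path("frame_t2.svg")
out.write_text(svg, encoding="utf-8")

sl = slice_at_time(traj, t)
print(f"wrote {out} ({len(svg)} bytes)")
print(f"displayed time point: t = {sl.time:g} s with {len(sl.records)} structures")
print(f"sum of occupancies: {sl.sum_occupancy:.4f}")
print("occupancies left to right:", [round(r.occupancy, 4) for r in sl.records])
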