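# cofoldviz

Batch visualization of cotranscriptional RNA folding trajectories.

RNA molecules fold while they are being transcribed, and simulators of
this process (heuristic, stochastic, or coarse-grained) emit time
courses: at each time point, a set of secondary structures with
occupancies — the fraction of the ensemble each structure holds — over a
transcript that grows during transcription. Read as raw tables these
files hide the interesting events: which helices compete, when the
dominant structure changes, and whether a functional conformation forms
during or only after transcription. `cofoldviz` is a library (plus a
thin CLI) for people running such simulations: it parses the trajectory
format, and renders composite SVG figures and animations that show the
occupancy-weighted ensemble at any time point together with a
whole-simulation overview.

The core conventions:

* **Pair coloring.** Every base pair (i, j) is colored by its imaginary
  center c = (i+j)/2 via `H(c) = (⌊c/9⌋ + 160c) mod 360`. Adjacent
  centers (0.5 apart, e.g. across a 1-nt bulge) differ by 80° of hue,
  cycling through nine base colors, so helices stay recognizable across
  panels and time points; perfectly aligned helices (equal centers)
  share a color.
* **Occupancy treemap.** The structures at a time point tile a panel
  with tile area ∝ occupancy, decreasing left to right; the displayed
  ensemble fraction is annotated as the sum of occupancies.
* **Composite time axis.** Time maps to [0, 1] with the end of
  transcription pinned at 0.75: linear during transcription, logarithmic
  afterwards, so the short cotranscriptional phase keeps most of the
  width however long the simulation runs.
* **Overview strip.** For each time point, the per-nucleotide colors of
  the most occupied structure are plotted as a column (5′ end at the
  bottom), making changes of the dominant structure visible at a glance.

Input is a whitespace-separated file whose header contains
`id time occupancy structure energy`; dot-bracket structures may use the
bracket layers `() [] {} <>` for pseudoknots, and a sequence (raw or
FASTA) can be supplied separately to letter the drawings.

## Worked example

```python
from cofoldviz import (RenderConfig, generate_fixture, render_frame,
                       slice_at_time, summary_table, transcription_end_time)

traj = generate_fixture("helix-competition", seed=1, n_timepoints=12, final_length=30)
print(transcription_end_time(traj))      # 3.0  (s; transcript reaches 30 nt)

table = summary_table(slice_at_time(traj, 2.0))
for row in table.rows:
    print(row.id, f"{row.occupancy:.4f}", row.structure)
print(f"sum of occupancies: {table.sum_occupancy:.4f}")

svg = render_frame(traj, 2.0, RenderConfig(min_occupancy=0.01))
open("frame.svg", "w").write(svg)
```

prints

```
3.0
0 0.4923 (((((((....))))))).
1 0.4923 (((((((.....)))))))
2 0.0154 ...................
sum of occupancies: 1.0000
```

At t = 2.0 s (displayed time point 1.9 s) the 5′-proximal hairpin
(id 0) and the long-range helix (id 1) each hold 49.2% of the ensemble —
the moment the dominant structure switches — with 1.5% unfolded; the
written SVG shows the three structures as treemap tiles above the
overview strip, whose black marker sits at 75% of the axis width (the
end of transcription at 3 s) and whose red cursor marks 1.9 s. The
`examples/` directory has one short script per capability (parsing and
summaries, the color scheme, the time axis, frame rendering, and
animation).

The same operations are available from a shell:

```sh
cofoldviz fixtures --preset helix-competition --seed 1 --out traj.txt
cofoldviz validate --input traj.txt
cofoldviz summary  --input traj.txt --time 2.0
cofoldviz render   --input traj.txt --time 2.0 --out frame.svg
cofoldviz animate  --input traj.txt --outdir frames --gif anim.gif --speed 4
```

See `docs/methods.md` for the model, parameter defaults, and the design
choices behind the geometry.

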