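# Methods

`cofoldviz` renders the time course of a cotranscriptional RNA folding
simulation: at every reported time point the simulation output is a small
ensemble of secondary structures with occupancies (ensemble fractions),
over a transcript that grows during transcription and is constant
afterwards. The package turns such a trajectory into composite figures —
a treemap of structure drawings for one time point above a
whole-simulation overview strip — and into frame-series animations.

## Input model

A trajectory file is a whitespace-separated table whose header must
contain `id time occupancy structure energy` (any order, extra columns
ignored, `#` comments allowed). `id` labels a structure lineage across
transcript lengths; `structure` is dot-bracket with up to four bracket
alphabets `() [] {} <>`, each alphabet an independently nested pseudoknot
layer. Letters as pseudoknot brackets are rejected: the fixed four-layer
alphabet keeps the grammar unambiguous and covers helix-level simulators
that emit knotted structures. Positions are 1-based everywhere, so the
smallest pair (1, 2) has imaginary center 1.5.

Validation is deliberately tolerant where simulator output is imperfect:
per-time-point occupancy sums above 1 + 1e-6 and duplicate ids within a
time point warn rather than fail, because aggregated stochastic
trajectories often need preprocessing and may carry rounding artifacts.
A shrinking transcript, by contrast, is a hard error — transcription can
only grow the chain — and an attached sequence must cover the longest
structure. Mixed structure lengths within one time point are allowed;
shorter structures are treated as unpaired beyond their length in the
overview strip.

Since the format carries no transcript-length column, the end of
transcription is detected as the first time point at which the maximum
structure length reaches its file-wide maximum. Arbitrary query times
resolve to the nearest previous time point (scrubbing-cursor semantics).

## Pair coloring

Each base pair (i, j) is colored by its imaginary center c = (i+j)/2:

    H(c) = (floor(c/9) + 160 c) mod 360

Centers move in half-integer steps (the smallest shift, 0.5, is a 1-nt
bulge), so adjacent centers are 80° apart in hue and the base term
160·c mod 360 cycles through exactly nine hues; the floor(c/9) term
slowly rotates that cycle along the sequence. The formula is implemented
exactly as stated, including the offset term; note that it does admit hue
collisions between well-separated centers (e.g. H(1.0) = H(5.5) = 160),
so no global non-repetition property is asserted. Hue is realized on the
standard HSL circle at fixed saturation 0.85 and lightness 0.45; unpaired
nucleotides are neutral gray (`#999999`), a choice the scheme itself
leaves open. All pairs of a perfect helix share one center and hence one
color, and two helices aligned on the same center share a color by
design.

## Time axis

The horizontal axis maps time to a fraction x ∈ [0, 1] with the end of
transcription pinned at x = 0.75: linear from the first time point t0 to
the transcription end t_end over the first 75% of the width, then
logarithmic from t_end to the last time point t_max,

    x(t) = 0.75 (t − t0)/(t_end − t0)                       t ≤ t_end
    x(t) = 0.75 + 0.25 ln(t/t_end) / ln(t_max/t_end)        t > t_end

This reserves most of the width for the comparatively short
cotranscriptional phase regardless of how long the simulation continues.
The logarithmic interpolation on the second segment is the natural map
consistent with a pinned 75% split; an exact closed-form inverse is
provided and round-trips to 1e-9. Degenerate trajectories are kept
well-defined rather than rejected: if the simulation stops at the end of
transcription the axis is fully linear; if no growth is observed the
axis is fully logarithmic from the first positive time point. Tick
placement (about five even ticks on the linear part, decade ticks on the
log part) is cosmetic.

## Treemap

Displayed structures at a time point are sorted by descending occupancy
(ties by ascending id) and tiled into the structure panel with tile area
proportional to occupancy. Tiling is relative — tiles always fill the
panel, and the displayed fraction of the ensemble is communicated by the
sum-of-occupancies annotation (printed with 4 decimals), not by empty
space — so even a slice holding a few percent of the ensemble stays
readable. Tiles are grouped into vertical strips advancing left to
right, which makes tile left edges follow the occupancy ordering
exactly; within that constraint strip membership follows the squarified
heuristic (Bruls, Huizing & van Wijk), keeping aspect ratios near 1.
Only area, ordering, containment, and non-overlap are contractual; tile
shapes are cosmetic.

## Structure layout

Structure drawings use a deterministic re-implementation of
force-directed secondary-structure layout: a radial nested-loop
construction (each loop a circle sized so adjacent members sit one unit
apart, each helix a pair of parallel rails extending outward) provides
initial coordinates, followed by 200 seeded relaxation iterations with
unit-rest-length springs on backbone and pair edges (stiffness 1.0),
short-range repulsion between non-adjacent nodes (strength 0.05, cutoff
2.5 rest lengths), and a decaying step-size cap. Pseudoknot pairs act as
springs but are excluded from the radial nesting, so knotted pairs
appear as extra edges over a nested drawing — standard practice for
knotted structures. A small seeded jitter (σ = 0.01) breaks symmetry;
single nucleotides skip relaxation and sit at the origin. The contract
is legibility and bitwise reproducibility per (structure, seed), not
visual equivalence with any interactive drawing engine. After
relaxation, backbone and pair distances stay within a few percent of
rest length for structures up to 200 nt, comfortably inside the 0.5–2×
band the tests assert. Drawings are scaled into their treemap tile
preserving aspect ratio with an 8–10% margin.

## Overview strip

For each time point the most occupied structure (ties → lowest id) is
colored per nucleotide and drawn as one column, position 1 (5′ end) at
the bottom and the transcript growing upward; cells beyond the current
transcript length use the background color. Each column spans from its
time point's x position to the next time point's (the last column to
x = 1), a step-function convention reflecting that simulation output is
piecewise constant between reported times; the columns therefore tile
[x(t_first), 1] with no gaps or overlaps.

## Rendering and animation

A frame is a standalone SVG 1.1 document with no external references:
the treemap panel of colored structure drawings, the annotation line
(current time; sum of displayed occupancies with 4 decimals), the
overview strip, a black vertical marker at the end-of-transcription
position (exactly 75% of axis width whenever the simulation continues
past transcription), and a red cursor at the displayed time point. The
marker and cursor carry stable element ids
(`transcription-end-marker`, `time-cursor`) so downstream tooling can
locate them. Filtering by `min_occupancy` (default 0.01; with occupancy
sums ≤ 1 at most 100 structures can then pass per time point) happens
inside the renderer, so pre-filtering and per-frame filtering commute.
Frames are byte-identical for identical inputs, configuration, and seed;
per-structure layout seeds are derived from the configured seed and a
CRC of the structure string, so the same conformation is drawn the same
way in every frame.

An animation is one frame per displayed time point in time order with
frame duration 1000/speed ms. SVG is the canonical output; a GIF can be
assembled by rasterizing the same display list with Pillow. The
interactive skip rule for scrubbing is exposed as the pure function
`min_dwell_time(m) = 5·m` ms, with m the maximal number of structures
per time point of the file (a single constant per file) and
`min_dwell_time(0) = 0` so empty selections are never suppressed.

## Synthetic trajectories

`generate_fixture` emulates simulator output for a transcript elongating
at 10 nt/s from 8 nt to the requested final length: 75% of the time
points are linearly spaced over transcription, 25% log-spaced over three
further decades. Competing conformations are idealized — a 5′-proximal
hairpin (stem capped at 8 bp), a long-range terminal helix, and an open
chain — with occupancies trading off through a logistic switch
(timescale 0.15·t_switch) plus a small uniformly drawn unfolded fraction
(1–5%); occupancies sum to 1 exactly and energies are −2 kcal/mol per
pair with small noise. The presets place the dominance switch
mid-transcription (`helix-competition`), after transcription
(`late-refold`), or nowhere (`single-hairpin`, one structure at
occupancy 1). Everything is deterministic per seed.

What the generator does not emulate: thermodynamically consistent
energies, realistic structural diversity (dozens of lineages, partial
helices, multiloops), occupancy noise from finite stochastic sampling,
or time points with occupancy sums below 1. Tests passing on these
fixtures demonstrate the geometry, coloring, ordering, and determinism
contracts of the pipeline — not that real simulator output will be
biologically interpreted correctly.

## Problem sizes and defaults

Default figures are 960×720 with a 40-unit margin and a 28% overview
strip; the test and acceptance workloads use 6–14 time points and
transcripts of 12–40 nt (plus one 200 nt layout check), sizes chosen so
a single figure renders in well under a second while still exercising
composite axes, pseudoknots, and multi-structure slices.

## Known limitations

* The dwell-time rule is exposed as a pure function only; there is no
  interactive scrubbing loop to apply it to.
* GIF rasterization uses Pillow's default font and simple stroke
  rendering; SVG output is the reference.
* Structures longer than a few hundred nucleotides make the O(n²)
  repulsion step and the per-nucleotide circles slow and visually dense;
  the layout remains correct but is not optimized for long transcripts.
* The occupancy filter drops entire trajectories (with an error) when
  nothing passes the threshold, mirroring the fact that a visualization
  with zero time points has no meaningful output.
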