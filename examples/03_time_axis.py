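"""The composite linear/logarithmic time axis.

Cotranscriptional folding is short compared to the equilibration that
follows, so the axis gives the transcription phase the first 75% of its
width (linear in time) and the remainder a logarithmic scale up to the
last time point.  The end of transcription is always pinned at x = 0.75.
"""

import math

from cofoldviz import TimeAxis, generate_fixture, transcription_end_time

traj = generate_fixture("helix-competition", seed=1, n_timepoints=12, final_length=30)
axis = TimeAxis.from_trajectory(traj)
t_end = transcription_end_time(traj)

print(f"t0 = {axis.t0} s, end of transcription = {axis.t_end} s, t_max = {axis.t_max} s\n")
print("time [s]   axis fraction x")
probe = [axis.t0, (axis.t0 + t_end) / 2, t_end, math.sqrt(t_end * axis.t_max), axis.t_max]
for t in probe:
    print(f"{t:<10.4g} {axis.time_to_x(t):.4f}")
print("\n-> x(t_end) = 0.75 exactly; the geometric mean of t_end and t_max")
print("   lands at 0.875, i.e. halfway through the logarithmic segment.")
print(f"   Inverse map: x=0.75 -> t = {axis.x_to_time(0.75):.4g} s (round trips to t_end).")
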