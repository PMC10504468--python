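"""Parse a trajectory file and inspect the ensemble at one time point.

Generates a small synthetic simulation of two competing helices, writes
it in the trajectory file format, parses it back, and prints the summary
table at t = 2 s: one row per displayed structure (most occupied first)
plus the sum of occupancies, i.e. the fraction of the ensemble shown.
"""

from cofoldviz import (
    generate_fixture,
    parse_trajectory,
    slice_at_time,
    summary_table,
    transcription_end_time,
    write_trajectory,
)

traj = parse_trajectory(write_trajectory(
    generate_fixture("helix-competition", seed=1, n_timepoints=12, final_length=30)
))
print(f"{len(traj)} records at {len(traj.times)} time points; "
      f"final transcript length {traj.max_length} nt; "
      f"transcription ends at t = {transcription_end_time(traj)} s\n")

table = summary_table(slice_at_time(traj, 2.0))
print("id  time    occupancy  structure")
for row in table.rows:
    print(f"{row.id:<3} {row.time:<7g} {row.occupancy:<10.4f} {row.structure}")
print(f"\nsum of occupancies: {table.sum_occupancy:.4f}  "
      "(fraction of the ensemble that would be displayed)")
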