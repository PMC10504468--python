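"""Synthetic cotranscriptional folding trajectories for tests and demos.

The generator emulates the output of a cotranscriptional folding
simulator for a transcript that grows at a fixed polymerase speed and
then equilibrates: 75% of the time points fall in the transcription
phase (linearly spaced, transcript length growing from 8 nt to the final
length) and 25% afterwards (log-spaced over three decades, length
constant).  Structures are idealized competing conformations — a
5'-proximal hairpin versus a long-range terminal helix — whose
occupancies trade off through a logistic switch, plus a small
open-chain background population.  Occupancies at every time point sum
to 1 and all presets are deterministic per seed.

Presets
-------
``single-hairpin``
    One structure per time point at occupancy 1: a hairpin that grows
    with the transcript.
``helix-competition``
    The dominant id switches from the hairpin to the long-range helix
    midway through transcription.
``late-refold``
    The hairpin dominates the whole transcription phase; the long-range
    helix takes over only well after transcription has ended.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ParameterError
from .trajectory_io import Trajectory, TrajectoryRecord

PRESETS = ("single-hairpin", "helix-competition", "late-refold")

#: Transcription speed used to convert transcript length to time, nt/s.
POLYMERASE_SPEED = 10.0
#: Decades of post-transcriptional simulation time.
POST_DECADES = 3.0
#: Shortest transcript in a generated file, nt.
MIN_LENGTH = 8


def _hairpin(length: int) -> str:
    """5'-proximal hairpin; the stem stops growing at 8 pairs."""
    stem = min((length - 4) // 2, 8)
    loop = 4
    tail = length - 2 * stem - loop
    if tail < 0:
        loop += tail
        tail = 0
    return "(" * stem + "." * loop + ")" * stem + "." * tail


def _long_range(length: int) -> str:
    """Helix pairing the 5' start with the 3' end (rod-like conformation)."""
    stem = min(length // 2 - 2, 8)
    return "(" * stem + "." * (length - 2 * stem) + ")" * stem


def _open_chain(length: int) -> str:
    return "." * length


def _energy(structure: str, rng: np.random.Generator) -> float:
    """Idealized stability: -2 kcal/mol per pair with small noise."""
    n_pairs = structure.count("(")
    return round(-2.0 * n_pairs + float(rng.normal(scale=0.3)), 2)


def generate_fixture(
    preset: str, seed: int, n_timepoints: int = 12, final_length: int = 30
) -> Trajectory:
    """Generate a valid synthetic trajectory.

    Parameters
    ----------
    preset:
        One of :data:`PRESETS`.
    seed:
        Seed for the (small) stochastic components; identical preset and
        seed give identical trajectories.
    n_timepoints:
        Total number of time points (>= 2); 75% during transcription.
    final_length:
        Final transcript length in nucleotides (>= 8).
    """
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if n_timepoints < 2:
        raise ParameterError("n_timepoints must be >= 2")
    if final_length < MIN_LENGTH:
        raise ParameterError(f"final_length must be >= {MIN_LENGTH}")
    rng = np.random.default_rng(seed)

    n_tx = max(2, math.ceil(0.75 * n_timepoints))
    n_post = n_timepoints - n_tx
    t_start = MIN_LENGTH / POLYMERASE_SPEED
    t_end = final_length / POLYMERASE_SPEED
    tx_times = np.linspace(t_start, t_end, n_tx)
    lengths = np.round(np.linspace(MIN_LENGTH, final_length, n_tx)).astype(int)
    post_times = t_end * 10.0 ** np.linspace(
        POST_DECADES / max(n_post, 1), POST_DECADES, n_post
    )
    times = np.concatenate([tx_times, post_times])
    all_lengths = np.concatenate([lengths, np.full(n_post, final_length, dtype=int)])

    if preset == "helix-competition":
        t_switch = float(tx_times[n_tx // 2])
    else:
        # switch placed after the end of transcription (unused by single-hairpin)
        t_switch = t_end * 10.0 ** (POST_DECADES / 2)
    tau = 0.15 * t_switch

    records: list[TrajectoryRecord] = []
    for t, length in zip(times, all_lengths):
        t = float(t)
        length = int(length)
        if preset == "single-hairpin":
            s = _hairpin(length)
            records.append(
                TrajectoryRecord(id=0, time=t, occupancy=1.0, structure=s, energy=_energy(s, rng))
            )
            continue
        w = 1.0 / (1.0 + math.exp(-(t - t_switch) / tau))
        minor = float(rng.uniform(0.01, 0.05))
        occ = {
            0: (1.0 - w) * (1.0 - minor),  # hairpin lineage
            1: w * (1.0 - minor),  # long-range helix lineage
            2: minor,  # unfolded background
        }
        structures = {0: _hairpin(length), 1: _long_range(length), 2: _open_chain(length)}
        for sid in sorted(occ):
            records.append(
                TrajectoryRecord(
                    id=sid,
                    time=t,
                    occupancy=occ[sid],
                    structure=structures[sid],
                    energy=_energy(structures[sid], rng),
                )
            )
    return Trajectory(records)
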