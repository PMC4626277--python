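"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately use plain Python loops so they stay
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from chaptraj.md_io import MolecularSystem, Trajectory

ELEMENTS = ("C", "N", "O", "S", "H")


def make_random_system(
    n_atoms: int,
    rng: np.random.Generator,
    n_residues: int | None = None,
    box_nm: float = 3.0,
    with_h: bool = True,
) -> MolecularSystem:
    n_residues = n_residues or max(1, n_atoms // 5)
    pool = ELEMENTS if with_h else ELEMENTS[:4]
    elements = tuple(rng.choice(pool) for _ in range(n_atoms))
    return MolecularSystem(
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=tuple(f"{e}{i}" for i, e in enumerate(elements)),
        elements=elements,
        residue_indices=np.sort(rng.integers(1, n_residues + 1, n_atoms)),
        residue_names=tuple("UNK" for _ in range(n_atoms)),
        chain_ids=tuple("A" for _ in range(n_atoms)),
        coords=rng.uniform(0, box_nm, (n_atoms, 3)),
    )


def make_random_trajectory(
    n_atoms: int, n_frames: int, rng: np.random.Generator, **kwargs
) -> Trajectory:
    system = make_random_system(n_atoms, rng, **kwargs)
    coords = rng.uniform(0, 3.0, (n_frames, n_atoms, 3))
    coords[0] = system.coords
    return Trajectory(
        system=system,
        times_ps=np.arange(n_frames, dtype=float),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# oracles


def brute_min_distance(xa, xb) -> float:
    best = math.inf
    for a in xa:
        for b in xb:
            d = math.dist(tuple(a), tuple(b))
            if d < best:
                best = d
    return best


def brute_min_image_distance(xa, xb, lengths) -> float:
    best = math.inf
    for a in xa:
        for b in xb:
            s = 0.0
            for k in range(3):
                d = a[k] - b[k]
                d -= lengths[k] * round(d / lengths[k])
                s += d * d
            best = min(best, math.sqrt(s))
    return best


def brute_count_contacts(xa, xb, cutoff) -> int:
    n = 0
    for a in xa:
        for b in xb:
            if math.dist(tuple(a), tuple(b)) < cutoff:
                n += 1
    return n


def brute_first_binding_time(events):
    """Scan over all attachment events; return the last one with no later
    detachment, or None."""
    result = None
    for i, e in enumerate(events):
        if e.kind != "attachment":
            continue
        if not any(x.kind == "detachment" for x in events[i + 1 :]):
            result = e.time_ps
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
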