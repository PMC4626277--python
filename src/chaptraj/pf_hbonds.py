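"""Backbone hydrogen bonds between beta-strand pairs (PF-contact statistic).

A bond is counted between a backbone N-H donor of one strand and a
backbone C=O acceptor of the other when the N...O distance and the
H-N...O angle satisfy the criterion; each donor is matched to at most its
nearest satisfying acceptor. When amide hydrogens are absent (crystal
structures), a distance-only fallback may be enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chaptraj.errors import StructureError
from chaptraj.md_io import MolecularSystem, Trajectory


@dataclass(frozen=True)
class HBondCriterion:
    donor_acceptor_max_nm: float = 0.35
    angle_max_deg: float = 30.0      # hydrogen-donor-acceptor angle
    heavy_only_fallback: bool = False

    def __post_init__(self) -> None:
        if self.donor_acceptor_max_nm <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_max_deg <= 90:
            raise ValueError("angle cutoff must lie in (0, 90] degrees")


@dataclass(frozen=True)
class StrandPair:
    strand_a: tuple[int, int]   # inclusive residue range
    strand_b: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        ra = set(range(self.strand_a[0], self.strand_a[1] + 1))
        rb = set(range(self.strand_b[0], self.strand_b[1] + 1))
        if ra & rb:
            raise ValueError("strand residue ranges must be disjoint")

    @classmethod
    def parse(cls, text: str) -> "StrandPair":
        """Parse '7-11:58-62' notation."""
        a, b = text.split(":")
        lo_a, hi_a = (int(v) for v in a.split("-"))
        lo_b, hi_b = (int(v) for v in b.split("-"))
        return cls(strand_a=(lo_a, hi_a), strand_b=(lo_b, hi_b), label=text)


@dataclass(frozen=True)
class HBond:
    donor_residue: int
    acceptor_residue: int
    distance_nm: float
    angle_deg: float | None


@dataclass(frozen=True)
class HBondReport:
    bonds: tuple[HBond, ...]

    @property
    def count(self) -> int:
        return len(self.bonds)


def _backbone_atoms(
    system: MolecularSystem, coords: np.ndarray, residues: range
):
    """Map residue -> {'N': xyz, 'H': xyz|None, 'O': xyz|None} for a strand."""
    out: dict[int, dict[str, np.ndarray | None]] = {
        r: {"N": None, "H": None, "O": None} for r in residues
    }
    for i in range(system.n_atoms):
        r = int(system.residue_indices[i])
        if r not in out:
            continue
        name = system.atom_names[i]
        if name == "N":
            out[r]["N"] = coords[i]
        elif name in ("H", "HN", "H1"):
            out[r]["H"] = coords[i]
        elif name == "O":
            out[r]["O"] = coords[i]
    return out


def _hda_angle_deg(h: np.ndarray, d: np.ndarray, a: np.ndarray) -> float:
    v1 = h - d
    v2 = a - d
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _directed_bonds(donors, acceptors, criterion: HBondCriterion) -> list[HBond]:
    """Bonds from N-H donors of one strand to C=O acceptors of the other."""
    bonds = []
    for dres, datoms in donors.items():
        n = datoms["N"]
        if n is None:
            continue
        h = datoms["H"]
        if h is None and not criterion.heavy_only_fallback:
            raise StructureError(
                f"residue {dres} lacks an amide hydrogen and "
                "heavy_only_fallback is disabled"
            )
        best: HBond | None = None
        for ares, aatoms in acceptors.items():
            o = aatoms["O"]
            if o is None:
                continue
            dist = float(np.linalg.norm(n - o))
            if dist > criterion.donor_acceptor_max_nm:
                continue
            if h is not None:
                ang = _hda_angle_deg(h, n, o)
                if ang > criterion.angle_max_deg:
                    continue
            else:
                ang = None
            if best is None or dist < best.distance_nm:
                best = HBond(dres, ares, dist, ang)
        if best is not None:
            bonds.append(best)
    return bonds


def backbone_hbonds(
    system: MolecularSystem,
    pair: StrandPair,
    criterion: HBondCriterion = HBondCriterion(),
    coords: np.ndarray | None = None,
) -> HBondReport:
    """Count backbone hydrogen bonds between the two strands, both directions."""
    coords = system.coords if coords is None else coords
    res_a = range(pair.strand_a[0], pair.strand_a[1] + 1)
    res_b = range(pair.strand_b[0], pair.strand_b[1] + 1)
    atoms_a = _backbone_atoms(system, coords, res_a)
    atoms_b = _backbone_atoms(system, coords, res_b)
    missing = [
        r
        for r, d in list(atoms_a.items()) + list(atoms_b.items())
        if d["N"] is None and d["O"] is None
    ]
    if missing:
        raise StructureError(
            f"backbone atoms missing for residues {sorted(set(missing))}"
        )
    bonds = _directed_bonds(atoms_a, atoms_b, criterion)
    bonds += _directed_bonds(atoms_b, atoms_a, criterion)
    return HBondReport(bonds=tuple(sorted(bonds, key=lambda b: b.donor_residue)))


@dataclass(frozen=True)
class PFContactSeries:
    pair: StrandPair
    times_ps: np.ndarray
    counts: np.ndarray

    def distribution(self) -> dict[int, float]:
        """Normalized distribution of the per-frame intact-bond count."""
        vals, freq = np.unique(self.counts, return_counts=True)
        total = freq.sum()
        return {int(v): float(c) / total for v, c in zip(vals, freq)}


def pf_contact_series(
    traj: Trajectory,
    pairs: list[StrandPair],
    criterion: HBondCriterion = HBondCriterion(),
) -> list[PFContactSeries]:
    """Per-frame intact-bond counts for each strand pair across a trajectory."""
    out = []
    for pair in pairs:
        counts = np.empty(traj.n_frames, dtype=int)
        for f in range(traj.n_frames):
            counts[f] = backbone_hbonds(
                traj.system, pair, criterion, coords=traj.coords[f]
            ).count
        out.append(
            PFContactSeries(pair=pair, times_ps=traj.times_ps.copy(), counts=counts)
        )
    return out
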