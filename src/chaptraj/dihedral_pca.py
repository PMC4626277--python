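"""Dihedral principal component analysis.

Backbone phi/psi torsions are mapped to (cos, sin) pairs before PCA so
that angular periodicity does not distort the covariance structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chaptraj.errors import DegenerateInputError, StructureError
from chaptraj.md_io import MolecularSystem, Trajectory


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion (radians, IUPAC convention) of four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


@dataclass(frozen=True)
class DihedralSeries:
    """Per-frame phi/psi angles (radians) with an ensemble label per frame."""

    angles: np.ndarray          # (n_frames, n_angles), in (-pi, pi]
    angle_names: tuple[str, ...]
    labels: tuple[str, ...]     # one per frame

    def __post_init__(self) -> None:
        if self.angles.ndim != 2:
            raise ValueError("angles must be 2-D (frames x angles)")
        if len(self.labels) != self.angles.shape[0]:
            raise ValueError("one label per frame required")
        if np.any(self.angles <= -np.pi - 1e-9) or np.any(self.angles > np.pi + 1e-9):
            raise ValueError("angles must lie in (-pi, pi]")


def concatenate_series(series: list[DihedralSeries]) -> DihedralSeries:
    names = series[0].angle_names
    for s in series[1:]:
        if s.angle_names != names:
            raise ValueError("cannot concatenate series with different angles")
    return DihedralSeries(
        angles=np.vstack([s.angles for s in series]),
        angle_names=names,
        labels=tuple(l for s in series for l in s.labels),
    )


def _backbone_index(system: MolecularSystem):
    """residue -> {atom_name: atom index} for N, CA, C."""
    table: dict[int, dict[str, int]] = {}
    for i in range(system.n_atoms):
        name = system.atom_names[i]
        if name in ("N", "CA", "C"):
            table.setdefault(int(system.residue_indices[i]), {})[name] = i
    return table


def backbone_dihedrals(
    traj: Trajectory,
    residue_range: tuple[int, int],
    label: str = "",
) -> DihedralSeries:
    """Standard phi (C'-N-CA-C') and psi (N-CA-C'-N) torsions.

    Residues lacking a neighbour (chain termini or edges of the requested
    range) contribute no angle; the retained set is identical for every
    frame so concatenated ensembles stay aligned.
    """
    table = _backbone_index(traj.system)
    lo, hi = residue_range
    specs: list[tuple[str, tuple[int, int, int, int]]] = []
    for r in range(lo, hi + 1):
        if r not in table:
            raise StructureError(f"residue {r} has no backbone atoms")
        cur = table[r]
        prev = table.get(r - 1)
        nxt = table.get(r + 1)
        if not all(k in cur for k in ("N", "CA", "C")):
            raise StructureError(f"residue {r} missing N/CA/C backbone atoms")
        if prev is not None and "C" in prev:
            specs.append(
                (f"phi_{r}", (prev["C"], cur["N"], cur["CA"], cur["C"]))
            )
        if nxt is not None and "N" in nxt:
            specs.append(
                (f"psi_{r}", (cur["N"], cur["CA"], cur["C"], nxt["N"]))
            )
    if not specs:
        raise StructureError("no complete phi/psi torsions in range")
    angles = np.empty((traj.n_frames, len(specs)))
    for f in range(traj.n_frames):
        x = traj.coords[f]
        for k, (_, (a, b, c, d)) in enumerate(specs):
            angles[f, k] = dihedral_angle(x[a], x[b], x[c], x[d])
    return DihedralSeries(
        angles=angles,
        angle_names=tuple(name for name, _ in specs),
        labels=tuple(label for _ in range(traj.n_frames)),
    )


@dataclass(frozen=True)
class DPCAResult:
    eigenvalues: np.ndarray      # descending
    eigenvectors: np.ndarray     # columns, orthonormal
    projections: np.ndarray      # (n_frames, k)
    labels: tuple[str, ...]
    covariance_trace: float
    feature_names: tuple[str, ...]


def dpca(series: DihedralSeries, n_components: int = 15) -> DPCAResult:
    """PCA on the sin/cos-transformed dihedral angles.

    Each angle theta contributes the pair (cos theta, sin theta). The
    covariance matrix of these 2*n_angles variables is diagonalized;
    eigenpairs are sorted by descending eigenvalue and each eigenvector's
    sign is fixed so its largest-magnitude component is positive.
    """
    n_frames, n_angles = series.angles.shape
    if n_frames < 2:
        raise DegenerateInputError("dpca requires at least 2 frames")
    n_feat = 2 * n_angles
    k = min(n_components, n_feat)
    feats = np.empty((n_frames, n_feat))
    feats[:, 0::2] = np.cos(series.angles)
    feats[:, 1::2] = np.sin(series.angles)
    feature_names = tuple(
        f"{fn}_{name}" for name in series.angle_names for fn in ("cos", "sin")
    )
    centered = feats - feats.mean(axis=0)
    cov = centered.T @ centered / (n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        i_max = np.argmax(np.abs(evecs[:, j]))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    projections = centered @ evecs[:, :k]
    return DPCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=projections,
        labels=series.labels,
        covariance_trace=float(np.trace(cov)),
        feature_names=feature_names,
    )
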