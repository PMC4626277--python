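"""Conformational observables: Rg, COM distances, RMSF, SASA, native contacts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from chaptraj.errors import (
    DegenerateInputError,
    ParameterError,
    SelectionError,
)
from chaptraj.md_io import MolecularSystem, SelectionSpec, Trajectory, resolve_selection

#: van der Waals radii (nm) for SASA
VDW_RADII_NM = {"C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "H": 0.12}
PROBE_RADIUS_NM = 0.14
NATIVE_CUTOFF_NM = 0.8   # default C-alpha native-contact cutoff; configurable
NATIVE_MIN_SEQ_SEP = 3


@dataclass(frozen=True)
class MetricSeries:
    name: str
    times_ps: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.times_ps) != len(self.values):
            raise ValueError("times/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite metric values")


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def radius_of_gyration(
    traj: Trajectory, sel: np.ndarray, mass_weighted: bool = True
) -> MetricSeries:
    """Rg = sqrt( sum m_i |r_i - r_com|^2 / sum m_i ) per frame, in nm."""
    sel = np.asarray(sel, dtype=int)
    if sel.size == 0:
        raise SelectionError("empty selection for radius_of_gyration")
    masses = traj.system.masses[sel] if mass_weighted else np.ones(sel.size)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coords[f, sel]
        com = _com(x, masses)
        values[f] = np.sqrt(
            (masses * ((x - com) ** 2).sum(axis=1)).sum() / masses.sum()
        )
    return MetricSeries("radius_of_gyration", traj.times_ps.copy(), values, "nm")


def com_distance(traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray) -> MetricSeries:
    """Distance between mass-weighted centres of two selections, per frame."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise SelectionError("empty selection for com_distance")
    ma = traj.system.masses[sel_a]
    mb = traj.system.masses[sel_b]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        values[f] = np.linalg.norm(
            _com(traj.coords[f, sel_a], ma) - _com(traj.coords[f, sel_b], mb)
        )
    return MetricSeries("com_distance", traj.times_ps.copy(), values, "nm")


# ---------------------------------------------------------------------------
# RMSF


def kabsch_rotation(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix superposing centred ``mobile`` onto centred ``ref``."""
    h = mobile.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    return u @ corr @ vt


def superpose_frames(coords: np.ndarray) -> np.ndarray:
    """Least-squares superpose every frame onto the ensemble mean.

    One fixed-point iteration: mean -> fit all frames -> recompute mean ->
    fit again. Returns the fitted coordinate array.
    """
    fitted = coords - coords.mean(axis=1, keepdims=True)
    for _ in range(2):
        mean = fitted.mean(axis=0)
        mean = mean - mean.mean(axis=0)
        out = np.empty_like(fitted)
        for f in range(fitted.shape[0]):
            r = kabsch_rotation(fitted[f], mean)
            out[f] = fitted[f] @ r
        fitted = out
    return fitted


def rmsf(traj: Trajectory, sel: np.ndarray, superpose: bool = True) -> np.ndarray:
    """Per-atom RMSF (nm) about the mean structure after superposition."""
    sel = np.asarray(sel, dtype=int)
    if sel.size == 0:
        raise SelectionError("empty selection for rmsf")
    if traj.n_frames < 2:
        raise DegenerateInputError("rmsf requires at least 2 frames")
    x = traj.coords[:, sel, :].copy()
    if superpose:
        x = superpose_frames(x)
    mean = x.mean(axis=0)
    return np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf_per_residue(
    traj: Trajectory, spec: SelectionSpec | None = None, superpose: bool = True
) -> dict[int, float]:
    """RMSF of C-alpha atoms keyed by residue index."""
    spec = spec or SelectionSpec(name="c_alpha", atom_filter="c_alpha")
    idx = resolve_selection(traj.system, spec)
    values = rmsf(traj, idx, superpose=superpose)
    resids = traj.system.residue_indices[idx]
    return {int(r): float(v) for r, v in zip(resids, values)}


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


@dataclass(frozen=True)
class SasaResult:
    total_nm2: float
    per_atom_nm2: np.ndarray
    per_residue_nm2: dict[int, float]


def sasa(
    system: MolecularSystem,
    coords: np.ndarray | None = None,
    sel: np.ndarray | None = None,
    probe_radius_nm: float = PROBE_RADIUS_NM,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    Deterministic for fixed ``n_points``: the test-point set is a
    Fibonacci sphere, not random sampling.
    """
    coords = system.coords if coords is None else coords
    sel = np.arange(system.n_atoms) if sel is None else np.asarray(sel, dtype=int)
    radii = np.empty(sel.size)
    for k, i in enumerate(sel):
        e = system.elements[i]
        if e not in VDW_RADII_NM:
            raise ParameterError(f"no van der Waals radius for element {e!r}")
        radii[k] = VDW_RADII_NM[e] + probe_radius_nm
    pts = _sphere_points(n_points)
    x = coords[sel]
    d2 = squareform(pdist(x)) ** 2
    per_atom = np.zeros(sel.size)
    for k in range(sel.size):
        # neighbours whose expanded sphere can intersect atom k's
        nbr = np.flatnonzero(d2[k] < (radii[k] + radii) ** 2)
        nbr = nbr[nbr != k]
        test = x[k] + radii[k] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in nbr:
            accessible &= ((test - x[j]) ** 2).sum(axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        per_atom[k] = 4.0 * np.pi * radii[k] ** 2 * accessible.sum() / n_points
    per_res: dict[int, float] = {}
    for k, i in enumerate(sel):
        r = int(system.residue_indices[i])
        per_res[r] = per_res.get(r, 0.0) + float(per_atom[k])
    return SasaResult(
        total_nm2=float(per_atom.sum()),
        per_atom_nm2=per_atom,
        per_residue_nm2=per_res,
    )


# ---------------------------------------------------------------------------
# native contacts


def native_contact_pairs(
    reference: MolecularSystem,
    cutoff_nm: float = NATIVE_CUTOFF_NM,
    min_seq_sep: int = NATIVE_MIN_SEQ_SEP,
) -> list[tuple[int, int]]:
    """C-alpha pairs (|i-j| >= min_seq_sep) within the cutoff in the reference."""
    ca = resolve_selection(
        reference, SelectionSpec(name="ref_ca", atom_filter="c_alpha")
    )
    resids = reference.residue_indices[ca]
    d = cdist(reference.coords[ca], reference.coords[ca])
    pairs = []
    for a in range(len(ca)):
        for b in range(a + 1, len(ca)):
            if abs(int(resids[a]) - int(resids[b])) >= min_seq_sep and d[a, b] < cutoff_nm:
                pairs.append((int(resids[a]), int(resids[b])))
    return pairs


def native_contact_fraction(
    traj: Trajectory,
    reference: MolecularSystem,
    cutoff_nm: float = NATIVE_CUTOFF_NM,
    min_seq_sep: int = NATIVE_MIN_SEQ_SEP,
) -> MetricSeries:
    """Q(frame): fraction of reference ('native') C-alpha contacts intact."""
    pairs = native_contact_pairs(reference, cutoff_nm, min_seq_sep)
    if not pairs:
        raise DegenerateInputError("reference has zero native contacts")
    ca = resolve_selection(
        traj.system, SelectionSpec(name="traj_ca", atom_filter="c_alpha")
    )
    res_to_atom = {
        int(traj.system.residue_indices[i]): i for i in ca
    }
    try:
        idx_pairs = [(res_to_atom[a], res_to_atom[b]) for a, b in pairs]
    except KeyError as exc:
        raise SelectionError(
            f"trajectory lacks C-alpha for residue {exc.args[0]}"
        ) from exc
    ia = np.array([p[0] for p in idx_pairs])
    ib = np.array([p[1] for p in idx_pairs])
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = np.linalg.norm(traj.coords[f, ia] - traj.coords[f, ib], axis=1)
        values[f] = (d < cutoff_nm).mean()
    return MetricSeries("native_contact_fraction", traj.times_ps.copy(), values, "")
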