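"""Synthetic ground-truth generators.

Every generator is deterministic given its seed. They produce the inputs
the analysis stages consume — two-state minimum-distance traces with known
transition times, overdamped Langevin pulling ensembles on analytic
potentials (known PMF), idealized antiparallel beta-strand geometries with
a constructed hydrogen-bond count, and dihedral ensembles around known
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from chaptraj.contact_kinetics import DistanceSeries, EventRecord
from chaptraj.dihedral_pca import DihedralSeries
from chaptraj.errors import IntegrationError, ParameterError
from chaptraj.md_io import MolecularSystem, Trajectory
from chaptraj.smd_pmf import PullTrace

# ---------------------------------------------------------------------------
# two-state binding traces


@dataclass(frozen=True)
class TwoStateSpec:
    rate_bind_per_ns: float = 0.5
    rate_unbind_per_ns: float = 0.2
    bound_mean_nm: float = 0.2
    unbound_mean_nm: float = 1.5
    noise_nm: float = 0.0       # half-width of uniform emission noise
    duration_ns: float = 100.0
    dt_ps: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_bind_per_ns <= 0 or self.rate_unbind_per_ns < 0:
            raise ParameterError("rates must be positive (unbind may be zero)")
        if self.bound_mean_nm >= 0.4:
            raise ParameterError("bound emission mean must lie below 0.4 nm")
        if self.unbound_mean_nm <= 1.0:
            raise ParameterError("unbound emission mean must lie above 1.0 nm")


@dataclass(frozen=True)
class BindingTrace:
    series: DistanceSeries
    true_events: tuple[EventRecord, ...]
    state_per_frame: np.ndarray   # 0 unbound, 1 bound


def gen_binding_trace(spec: TwoStateSpec) -> BindingTrace:
    """Continuous-time two-state chain sampled on a regular time grid.

    Starts unbound. The ground-truth event list holds one record per frame
    at which the sampled state differs from the previous frame's state, so
    it matches what a perfect detector would see on the grid.
    """
    rng = np.random.default_rng(spec.seed)
    duration_ps = spec.duration_ns * 1000.0
    times = np.arange(0.0, duration_ps + 0.5 * spec.dt_ps, spec.dt_ps)
    # exact CTMC transition times
    transitions: list[float] = []
    t, state = 0.0, 0
    while t < duration_ps:
        rate = spec.rate_bind_per_ns if state == 0 else spec.rate_unbind_per_ns
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate) * 1000.0
        if t < duration_ps:
            transitions.append(t)
            state = 1 - state
    # state on the grid: parity of transitions that happened by each time
    trans_arr = np.asarray(transitions)
    states = (np.searchsorted(trans_arr, times, side="right") % 2).astype(int)
    values = np.where(
        states == 1, spec.bound_mean_nm, spec.unbound_mean_nm
    ).astype(float)
    if spec.noise_nm > 0:
        values = values + rng.uniform(-spec.noise_nm, spec.noise_nm, len(values))
        values = np.clip(values, 0.0, None)
    change = np.flatnonzero(np.diff(states) != 0) + 1
    events = [
        EventRecord(
            "attachment" if states[i] == 1 else "detachment", float(times[i]), int(i)
        )
        for i in change
    ]
    return BindingTrace(
        series=DistanceSeries(times_ps=times, values_nm=values),
        true_events=tuple(events),
        state_per_frame=states,
    )


# ---------------------------------------------------------------------------
# Langevin pulling ensembles


@dataclass(frozen=True)
class LangevinPullSpec:
    potential: Callable[[np.ndarray], np.ndarray] | None = None
    potential_grad: Callable[[np.ndarray], np.ndarray] | None = None
    harmonic_k0: float = 0.0            # used when no callable is given
    spring_constant: float = 1000.0     # kJ/mol/nm^2
    pull_speed_nm_per_ns: float = 1.0
    friction: float = 100.0             # kJ/mol * ps / nm^2
    temperature_k: float = 300.0
    n_curves: int = 20
    duration_ps: float = 1000.0
    dt_ps: float = 0.01
    output_stride: int = 1      # record every Nth step (integration stays fine)
    x0_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spring_constant", "friction", "duration_ps", "dt_ps"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.temperature_k < 0:
            raise ParameterError("temperature must be non-negative")
        # explicit Euler stability for the stiffest restoring force
        k_total = self.spring_constant + abs(self.harmonic_k0)
        if self.dt_ps >= 0.1 * self.friction / k_total:
            raise ParameterError(
                f"dt={self.dt_ps} ps too large; require dt < 0.1*friction/k_total"
                f" = {0.1 * self.friction / k_total:.4g} ps"
            )

    def grad(self, x: np.ndarray) -> np.ndarray:
        """dU/dx; callables must accept array input elementwise."""
        if self.potential_grad is not None:
            return np.asarray(self.potential_grad(x), dtype=float)
        return self.harmonic_k0 * np.asarray(x, dtype=float)

    def analytic_pmf(self, s: np.ndarray) -> np.ndarray:
        """Potential evaluated along the pulled coordinate (known PMF)."""
        if self.potential is not None:
            return np.asarray(self.potential(s), dtype=float)
        return 0.5 * self.harmonic_k0 * np.asarray(s, dtype=float) ** 2


@dataclass(frozen=True)
class PullEnsemble:
    traces: tuple[PullTrace, ...]
    exact_work: np.ndarray     # (n_curves, n_steps+1) accumulated on the fly
    spec: LangevinPullSpec


def gen_smd_ensemble(spec: LangevinPullSpec) -> PullEnsemble:
    """Overdamped Euler-Maruyama pulling with a moving harmonic anchor.

    Integrates gamma*dx = [-U'(x) - k(x - vt)] dt + sqrt(2 gamma kBT) dW and
    accumulates the Jarzynski work dW_t = -k (x - vt) * v dt alongside.
    """
    from chaptraj.smd_pmf import KB_KJ_PER_MOL_K

    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration_ps / spec.dt_ps))
    v = spec.pull_speed_nm_per_ns / 1000.0   # nm/ps
    kbt = KB_KJ_PER_MOL_K * spec.temperature_k
    noise_scale = np.sqrt(2.0 * kbt * spec.dt_ps / spec.friction)
    stride = max(1, int(spec.output_stride))
    rec_idx = np.arange(0, n_steps + 1, stride)
    times = np.arange(n_steps + 1) * spec.dt_ps
    anchors = spec.x0_nm + v * times
    d_anchor = np.diff(anchors)
    works = np.zeros((spec.n_curves, len(rec_idx)))
    xs = np.empty((spec.n_curves, len(rec_idx)))
    # vectorized over curves; the step loop stays serial (Markovian update)
    x = np.full(spec.n_curves, spec.x0_nm)
    xs[:, 0] = x
    w = np.zeros(spec.n_curves)
    k = spec.spring_constant
    rec = 1
    for i in range(n_steps):
        f_spring = -k * (x - anchors[i])
        drift = (-spec.grad(x) + f_spring) / spec.friction
        x_new = x + drift * spec.dt_ps + noise_scale * rng.standard_normal(
            spec.n_curves
        )
        # dH/dlambda * dlambda: work done by advancing the anchor
        w = w + k * d_anchor[i] * (anchors[i] - 0.5 * (x + x_new)) + (
            0.5 * k * d_anchor[i] ** 2
        )
        x = x_new
        if (i + 1) % stride == 0 or i + 1 == n_steps:
            if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e6):
                raise IntegrationError(
                    "Langevin integration diverged; reduce dt_ps"
                )
            if rec < len(rec_idx) and rec_idx[rec] == i + 1:
                xs[:, rec] = x
                works[:, rec] = w
                rec += 1
    traces = tuple(
        PullTrace(
            times_ps=times[rec_idx],
            coordinate_nm=xs[c],
            anchor_nm=anchors[rec_idx],
            spring_constant=spec.spring_constant,
            pull_speed_nm_per_ns=spec.pull_speed_nm_per_ns,
        )
        for c in range(spec.n_curves)
    )
    return PullEnsemble(traces=traces, exact_work=works, spec=spec)


# ---------------------------------------------------------------------------
# beta-hairpin fixture

_BOND_NM = 0.29       # canonical N...O donor-acceptor distance
_COLUMN_SPACING = 0.7  # wide enough that no cross-column pair can bond


def gen_beta_hairpin(
    n_bonds: int = 4,
    n_broken: int = 0,
    strand_a_residues: tuple[int, int] = (7, 11),
    strand_b_residues: tuple[int, int] = (58, 62),
    separation_nm: float = 0.0,
) -> MolecularSystem:
    """Idealized two-strand backbone with a constructed hydrogen-bond count.

    Builds two 5-residue antiparallel-style strands in which exactly
    ``n_bonds - n_broken`` canonical N-H...O=C geometries satisfy the
    default criterion (N...O = 0.29 nm, collinear H). ``n_broken`` bonds
    are broken by displacing the acceptor carbonyl 2 nm out of plane;
    ``separation_nm`` rigidly translates strand B away from strand A.
    """
    len_a = strand_a_residues[1] - strand_a_residues[0] + 1
    len_b = strand_b_residues[1] - strand_b_residues[0] + 1
    if n_bonds < 1 or n_bonds > len_a + len_b:
        raise ParameterError(f"n_bonds must lie in [1, {len_a + len_b}]")
    if not 0 <= n_broken <= n_bonds:
        raise ParameterError("n_broken must lie in [0, n_bonds]")
    atoms: list[tuple[str, str, int, str, np.ndarray]] = []

    def add_residue(resid: int, x: float, y_n: float, y_o: float, y_h: float, z: float = 0.0):
        # N, amide H, CA, C, carbonyl O; CA/C offset in x to stay inert
        atoms.append(("N", "N", resid, "ALA", np.array([x, y_n, z])))
        atoms.append(("H", "H", resid, "ALA", np.array([x, y_h, z])))
        atoms.append(("CA", "C", resid, "ALA", np.array([x + 0.15, y_n, z])))
        atoms.append(("C", "C", resid, "ALA", np.array([x + 0.25, y_o, z])))
        atoms.append(("O", "O", resid, "ALA", np.array([x, y_o, z])))

    n_cols = max(len_a, len_b)
    bonded_cols = list(range(n_bonds))
    broken_cols = set(bonded_cols[:n_broken])
    for j in range(n_cols):
        x = j * _COLUMN_SPACING
        res_a = strand_a_residues[0] + j
        res_b = strand_b_residues[0] + j
        bonded = j in bonded_cols
        a_is_donor = bonded and (j % 2 == 0)
        b_is_donor = bonded and (j % 2 == 1)
        # strand A at y ~ 0; strand B above at y ~ 0.5
        if j < len_a:
            if a_is_donor:
                # A donates: N at 0, H toward B; its own O points away
                add_residue(res_a, x, y_n=0.0, y_o=-0.3, y_h=0.1)
            elif b_is_donor:
                # A accepts: O raised toward B's N
                add_residue(res_a, x, y_n=0.0, y_o=0.5 - _BOND_NM, y_h=-0.1)
            else:
                add_residue(res_a, x, y_n=0.0, y_o=-0.3, y_h=-0.1)
        if j < len_b:
            if a_is_donor:
                # B accepts: O lowered toward A's N
                add_residue(res_b, x, y_n=0.5, y_o=_BOND_NM, y_h=0.6)
            elif b_is_donor:
                # B donates: N at 0.5, H toward A; own O points away
                add_residue(res_b, x, y_n=0.5, y_o=0.8, y_h=0.4)
            else:
                add_residue(res_b, x, y_n=0.5, y_o=0.8, y_h=0.6)
    coords = np.array([a[4] for a in atoms])
    resids = np.array([a[2] for a in atoms])
    # break selected bonds: push the acceptor O out of plane
    strand_b_set = set(range(strand_b_residues[0], strand_b_residues[1] + 1))
    for j in broken_cols:
        acceptor_res = (
            strand_b_residues[0] + j if j % 2 == 0 else strand_a_residues[0] + j
        )
        for i, a in enumerate(atoms):
            if a[2] == acceptor_res and a[0] == "O":
                coords[i] = coords[i] + np.array([0.0, 0.0, 2.0])
    if separation_nm:
        mask = np.isin(resids, sorted(strand_b_set))
        coords[mask] += np.array([0.0, separation_nm, 0.0])
    return MolecularSystem(
        atom_ids=np.arange(1, len(atoms) + 1),
        atom_names=tuple(a[0] for a in atoms),
        elements=tuple(a[1] for a in atoms),
        residue_indices=resids,
        residue_names=tuple(a[3] for a in atoms),
        chain_ids=tuple("A" for _ in atoms),
        coords=coords,
    )


def gen_hairpin_trajectory(
    n_frames: int = 10, dt_ps: float = 1.0, **kwargs
) -> Trajectory:
    """Static multi-frame trajectory over a hairpin fixture."""
    system = gen_beta_hairpin(**kwargs)
    coords = np.repeat(system.coords[None, :, :], n_frames, axis=0)
    return Trajectory(
        system=system,
        times_ps=np.arange(n_frames, dtype=float) * dt_ps,
        coords=coords,
    )


# ---------------------------------------------------------------------------
# dihedral ensembles


def gen_dihedral_ensembles(
    centroids: tuple[np.ndarray, np.ndarray],
    spread_deg: float,
    n_frames: int,
    seed: int = 0,
    labels: tuple[str, str] = ("ensemble_a", "ensemble_b"),
) -> tuple[DihedralSeries, DihedralSeries]:
    """Wrapped-normal dihedral samples around two centroids (radians)."""
    if spread_deg < 0:
        raise ParameterError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    spread = np.radians(spread_deg)
    out = []
    for centroid, label in zip(centroids, labels):
        centroid = np.asarray(centroid, dtype=float)
        samples = centroid[None, :] + spread * rng.standard_normal(
            (n_frames, len(centroid))
        )
        wrapped = np.mod(samples + np.pi, 2 * np.pi) - np.pi
        wrapped[wrapped == -np.pi] = np.pi
        out.append(
            DihedralSeries(
                angles=wrapped,
                angle_names=tuple(f"angle_{i}" for i in range(len(centroid))),
                labels=tuple(label for _ in range(n_frames)),
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# small 3-D two-cluster trajectories (end-to-end exercise of distance code)


def gen_two_cluster_trajectory(
    n_atoms_per_cluster: int = 20,
    n_frames: int = 20,
    gap_series_nm: np.ndarray | None = None,
    cluster_radius_nm: float = 0.15,
    dt_ps: float = 10.0,
    seed: int = 0,
) -> Trajectory:
    """Two compact atom clouds whose centre separation follows ``gap_series_nm``.

    Atoms 0..n-1 form molecule A (residue 1), the rest molecule B
    (residue 2); useful for exercising the 3-D minimum-distance path with
    an approximately known gap.
    """
    rng = np.random.default_rng(seed)
    if gap_series_nm is None:
        gap_series_nm = np.full(n_frames, 1.5)
    gap_series_nm = np.asarray(gap_series_nm, dtype=float)
    n_frames = len(gap_series_nm)
    local_a = rng.uniform(-cluster_radius_nm, cluster_radius_nm, (n_atoms_per_cluster, 3))
    local_b = rng.uniform(-cluster_radius_nm, cluster_radius_nm, (n_atoms_per_cluster, 3))
    coords = np.empty((n_frames, 2 * n_atoms_per_cluster, 3))
    for f, gap in enumerate(gap_series_nm):
        coords[f, :n_atoms_per_cluster] = local_a
        coords[f, n_atoms_per_cluster:] = local_b + np.array([gap, 0.0, 0.0])
    n_total = 2 * n_atoms_per_cluster
    system = MolecularSystem(
        atom_ids=np.arange(1, n_total + 1),
        atom_names=tuple("C" for _ in range(n_total)),
        elements=tuple("C" for _ in range(n_total)),
        residue_indices=np.array(
            [1] * n_atoms_per_cluster + [2] * n_atoms_per_cluster
        ),
        residue_names=tuple("UNK" for _ in range(n_total)),
        chain_ids=tuple(
            ["A"] * n_atoms_per_cluster + ["B"] * n_atoms_per_cluster
        ),
        coords=coords[0],
    )
    return Trajectory(
        system=system,
        times_ps=np.arange(n_frames, dtype=float) * dt_ps,
        coords=coords,
    )
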