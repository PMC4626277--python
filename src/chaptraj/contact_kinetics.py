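"""Inter-molecular contact kinetics.

Minimum-distance series, two-threshold (hysteresis) attachment/detachment
event detection, ensemble binding statistics, per-residue contact
probabilities, contact counting and hydrophilic contact fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from chaptraj.errors import (
    ConfigurationError,
    DegenerateInputError,
    SelectionError,
    ThresholdError,
)
from chaptraj.md_io import (
    MolecularSystem,
    SelectionSpec,
    Trajectory,
    iter_residue_atom_indices,
    resolve_selection,
)

ATTACH_NM = 0.4    # contact forms when min distance falls below this
DETACH_NM = 1.0    # contact breaks when min distance rises above this
CONTACT_NM = 0.4   # heavy-atom pair contact cutoff


@dataclass(frozen=True)
class DistanceSeries:
    """Minimum inter-selection distance over time."""

    times_ps: np.ndarray
    values_nm: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if len(self.times_ps) != len(self.values_nm):
            raise ValueError("times and values length mismatch")
        if not np.all(np.isfinite(self.values_nm)) or np.any(self.values_nm < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass(frozen=True)
class EventRecord:
    kind: str          # "attachment" | "detachment"
    time_ps: float
    frame_index: int


@dataclass(frozen=True)
class BindingKinetics:
    """Ensemble binding summary.

    ``tau_ns`` is the mean over trajectories of the time of the last
    attachment event not followed by any detachment; trajectories that end
    unbound have no first binding time and are only counted in
    ``n_unbound``. ``n_events`` counts completed attachment->detachment
    cycles (the number of detachment events).
    """

    tau_ns: float | None
    n_events: int
    first_binding_times_ns: tuple[float, ...]
    n_unbound: int


@dataclass(frozen=True)
class ContactSet:
    """Cross-selection atom-index pairs within the cutoff, one frame."""

    pairs: tuple[tuple[int, int], ...]
    cutoff_nm: float

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# distances


def _minimum_image(diff: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    return diff - box_lengths * np.round(diff / box_lengths)


def _frame_min_distance(
    xa: np.ndarray, xb: np.ndarray, box: np.ndarray | None
) -> float:
    if box is None:
        # KD-tree nearest neighbour equals the all-pairs minimum exactly:
        # both minimise the same Euclidean metric over the same pair set.
        if len(xa) * len(xb) > 10000:
            d, _ = cKDTree(xb).query(xa, k=1)
            return float(d.min())
        return float(cdist(xa, xb).min())
    diff = xa[:, None, :] - xb[None, :, :]
    diff = _minimum_image(diff, box[:3])
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def min_distance_series(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    use_pbc: bool = False,
    label_a: str = "A",
    label_b: str = "B",
) -> DistanceSeries:
    """Per-frame minimum distance between two disjoint atom selections."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise SelectionError("selections must be non-empty")
    if np.intersect1d(sel_a, sel_b).size:
        raise SelectionError("selections overlap")
    if use_pbc and traj.boxes is None:
        raise ConfigurationError("use_pbc requested but trajectory has no box")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        box = traj.boxes[f] if use_pbc else None
        if box is not None and not np.allclose(box[3:], 90.0):
            raise ConfigurationError("minimum-image only supports orthorhombic boxes")
        values[f] = _frame_min_distance(
            traj.coords[f, sel_a], traj.coords[f, sel_b], box
        )
    return DistanceSeries(
        times_ps=traj.times_ps.copy(),
        values_nm=values,
        label_a=label_a,
        label_b=label_b,
    )


# ---------------------------------------------------------------------------
# events


def detect_events(
    series: DistanceSeries,
    attach_nm: float = ATTACH_NM,
    detach_nm: float = DETACH_NM,
) -> list[EventRecord]:
    """Two-state hysteresis automaton over a minimum-distance series.

    Starts unbound. Attachment fires at the first frame strictly below
    ``attach_nm`` while unbound; detachment at the first frame strictly
    above ``detach_nm`` while bound. Values inside [attach, detach] (and
    exact threshold ties) never change state — the margin suppresses false
    detachments from brief excursions.
    """
    if attach_nm >= detach_nm:
        raise ThresholdError(
            f"attach threshold {attach_nm} must be < detach threshold {detach_nm}"
        )
    events: list[EventRecord] = []
    bound = False
    for i, (t, d) in enumerate(zip(series.times_ps, series.values_nm)):
        if not bound and d < attach_nm:
            events.append(EventRecord("attachment", float(t), i))
            bound = True
        elif bound and d > detach_nm:
            events.append(EventRecord("detachment", float(t), i))
            bound = False
    return events


def binding_kinetics(
    event_lists: list[list[EventRecord]],
    trajectory_lengths_ns: list[float] | None = None,
) -> BindingKinetics:
    """Ensemble binding statistics from per-trajectory event lists.

    Per trajectory, the first binding time is the time of the last
    attachment event with no subsequent detachment; trajectories ending
    unbound contribute no binding time. If no trajectory ever binds stably,
    ``tau_ns`` is None rather than zero.
    """
    first_times: list[float] = []
    n_unbound = 0
    n_detach = 0
    for events in event_lists:
        _check_alternating(events)
        n_detach += sum(1 for e in events if e.kind == "detachment")
        if events and events[-1].kind == "attachment":
            first_times.append(events[-1].time_ps / 1000.0)
        else:
            n_unbound += 1
    tau = float(np.mean(first_times)) if first_times else None
    return BindingKinetics(
        tau_ns=tau,
        n_events=n_detach,
        first_binding_times_ns=tuple(first_times),
        n_unbound=n_unbound,
    )


def _check_alternating(events: list[EventRecord]) -> None:
    expected = "attachment"
    last_t = -np.inf
    for e in events:
        if e.kind != expected:
            raise ValueError(
                "event list must alternate attachment/detachment starting "
                f"with attachment; got {e.kind!r}"
            )
        if e.time_ps < last_t:
            raise ValueError("events must be time-ordered")
        last_t = e.time_ps
        expected = "detachment" if expected == "attachment" else "attachment"


# ---------------------------------------------------------------------------
# contact probability and counting


def contact_probability(
    traj: Trajectory,
    probe: SelectionSpec,
    target: SelectionSpec,
    unit: str = "residue",
    cutoff_nm: float = CONTACT_NM,
    domains=None,
) -> dict:
    """Fraction of frames each probe unit is within ``cutoff_nm`` of the target.

    For each residue (or named domain) of the probe, the per-frame minimum
    heavy-atom distance to the whole target selection is computed; the
    probability is the fraction of frames below the cutoff, identical to
    the area of the normalized min-distance distribution below the cutoff.
    """
    if cutoff_nm <= 0:
        raise ThresholdError("cutoff must be positive")
    target_idx = resolve_selection(traj.system, target)
    result: dict = {}
    if unit == "residue":
        groups = list(iter_residue_atom_indices(traj.system, probe))
    elif unit == "domain":
        if domains is None:
            raise ConfigurationError("unit='domain' requires a DomainMap")
        groups = []
        for name, (lo, hi) in domains.items():
            spec = SelectionSpec(
                name=name, residue_range=(lo, hi), atom_filter=probe.atom_filter
            )
            groups.append((name, resolve_selection(traj.system, spec)))
    else:
        raise ConfigurationError(f"unknown unit {unit!r}")
    for key, idx in groups:
        below = 0
        for f in range(traj.n_frames):
            d = _frame_min_distance(
                traj.coords[f, idx], traj.coords[f, target_idx], None
            )
            if d < cutoff_nm:
                below += 1
        result[key] = below / traj.n_frames
    return result


def count_contacts(
    coords: np.ndarray,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    cutoff_nm: float = CONTACT_NM,
) -> tuple[int, ContactSet]:
    """Number of cross-selection atom pairs within the cutoff for one frame."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if np.intersect1d(sel_a, sel_b).size:
        raise SelectionError("selections overlap")
    d = cdist(coords[sel_a], coords[sel_b])
    ia, ib = np.nonzero(d < cutoff_nm)
    pairs = tuple(
        (int(sel_a[i]), int(sel_b[j])) for i, j in zip(ia, ib)
    )
    return len(pairs), ContactSet(pairs=pairs, cutoff_nm=cutoff_nm)


def contact_count_series(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    cutoff_nm: float = CONTACT_NM,
) -> tuple[np.ndarray, list[ContactSet]]:
    counts = np.empty(traj.n_frames, dtype=int)
    sets: list[ContactSet] = []
    for f in range(traj.n_frames):
        counts[f], cs = count_contacts(traj.coords[f], sel_a, sel_b, cutoff_nm)
        sets.append(cs)
    return counts, sets


# ---------------------------------------------------------------------------
# hydrophilic fraction


@dataclass(frozen=True)
class HydrophilicFraction:
    per_frame: tuple[float | None, ...]   # None where a frame has no contacts
    pooled: float
    n_contacts: int
    n_hydrophilic: int


def hydrophilic_fraction(
    contact_sets: list[ContactSet],
    system: MolecularSystem,
    frame_window: tuple[int, int] | None = None,
) -> HydrophilicFraction:
    """Share of contacts in which both atoms are nitrogen or oxygen.

    ``frame_window`` restricts the pooled statistic to a half-open frame
    slice (e.g. the first 10 ns of a run).
    """
    if frame_window is not None:
        pool = contact_sets[frame_window[0] : frame_window[1]]
    else:
        pool = contact_sets
    per_frame: list[float | None] = []
    total = hydro = 0
    for cs in contact_sets:
        if len(cs) == 0:
            per_frame.append(None)
            continue
        h = sum(
            1
            for a, b in cs.pairs
            if system.elements[a] in ("N", "O") and system.elements[b] in ("N", "O")
        )
        per_frame.append(h / len(cs))
    for cs in pool:
        total += len(cs)
        hydro += sum(
            1
            for a, b in cs.pairs
            if system.elements[a] in ("N", "O") and system.elements[b] in ("N", "O")
        )
    if total == 0:
        raise DegenerateInputError(
            "no contacts in the pooled window; hydrophilic fraction undefined"
        )
    return HydrophilicFraction(
        per_frame=tuple(per_frame),
        pooled=hydro / total,
        n_contacts=total,
        n_hydrophilic=hydro,
    )


# ---------------------------------------------------------------------------
# end-to-end metrics


@dataclass(frozen=True)
class EndToEndMetrics:
    times_ps: np.ndarray
    contact_counts: np.ndarray
    com_distance_nm: np.ndarray


def end_to_end_metrics(
    traj: Trajectory,
    chain: SelectionSpec,
    n_end: int = 5,
    cutoff_nm: float = CONTACT_NM,
) -> EndToEndMetrics:
    """Contacts and COM distance between the first and last n residues."""
    chain_res = sorted(
        {int(r) for r, _ in iter_residue_atom_indices(traj.system, chain)}
    )
    if len(chain_res) < 2 * n_end:
        raise SelectionError(
            f"chain has {len(chain_res)} residues; needs >= {2 * n_end}"
        )
    head = SelectionSpec(
        name="head", residues=tuple(chain_res[:n_end]), atom_filter="heavy"
    )
    tail = SelectionSpec(
        name="tail", residues=tuple(chain_res[-n_end:]), atom_filter="heavy"
    )
    idx_h = resolve_selection(traj.system, head)
    idx_t = resolve_selection(traj.system, tail)
    masses = traj.system.masses
    mh = masses[idx_h]
    mt = masses[idx_t]
    counts = np.empty(traj.n_frames, dtype=int)
    com_d = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        counts[f], _ = count_contacts(traj.coords[f], idx_h, idx_t, cutoff_nm)
        com_h = (traj.coords[f, idx_h] * mh[:, None]).sum(0) / mh.sum()
        com_t = (traj.coords[f, idx_t] * mt[:, None]).sum(0) / mt.sum()
        com_d[f] = np.linalg.norm(com_h - com_t)
    return EndToEndMetrics(
        times_ps=traj.times_ps.copy(), contact_counts=counts, com_distance_nm=com_d
    )
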