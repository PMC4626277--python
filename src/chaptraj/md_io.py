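"""Structure and trajectory I/O, selections and domain maps.

All coordinates are stored in nanometres; PDB input (Angstrom) is converted
on load. Residue numbering is 1-based and taken verbatim from the input
file; residue ranges are inclusive at both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from chaptraj.errors import (
    EmptyInputError,
    FormatError,
    SelectionError,
    TopologyError,
)

logger = logging.getLogger(__name__)

KNOWN_ELEMENTS = frozenset({"C", "N", "O", "S", "H"})

#: residue names dropped on load unless heteroatoms are requested
WATER_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP", "T3P", "T4P", "SPC"})
ION_NAMES = frozenset({"NA", "CL", "K", "MG", "CA", "ZN", "NA+", "CL-"})

#: standard masses (u) used for mass-weighted centres; fallback 12.0
ATOMIC_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "H": 1.008,
    "other": 12.0,
}


@dataclass(frozen=True)
class MolecularSystem:
    """Atoms with metadata plus one reference coordinate frame (nm)."""

    atom_ids: np.ndarray          # (n,) int
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]     # one of C,N,O,S,H,other
    residue_indices: np.ndarray   # (n,) int, 1-based file numbering
    residue_names: tuple[str, ...]
    chain_ids: tuple[str, ...]
    coords: np.ndarray            # (n, 3) float, nm

    def __post_init__(self) -> None:
        n = len(self.atom_ids)
        if n == 0:
            raise EmptyInputError("system has no atoms")
        if len(set(self.atom_ids.tolist())) != n:
            raise FormatError("atom ids are not unique")
        if np.any(self.residue_indices <= 0):
            raise FormatError("residue indices must be positive (1-based)")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        if self.coords.shape != (n, 3):
            raise FormatError("coordinate array shape mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def masses(self) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(e, ATOMIC_MASSES["other"]) for e in self.elements]
        )

    def residue_span(self) -> tuple[int, int]:
        return int(self.residue_indices.min()), int(self.residue_indices.max())

    def subset(self, atom_indices: Sequence[int]) -> "MolecularSystem":
        idx = np.asarray(atom_indices, dtype=int)
        return MolecularSystem(
            atom_ids=self.atom_ids[idx],
            atom_names=tuple(self.atom_names[i] for i in idx),
            elements=tuple(self.elements[i] for i in idx),
            residue_indices=self.residue_indices[idx],
            residue_names=tuple(self.residue_names[i] for i in idx),
            chain_ids=tuple(self.chain_ids[i] for i in idx),
            coords=self.coords[idx],
        )


@dataclass(frozen=True)
class Trajectory:
    """Frames of coordinates (nm) over a MolecularSystem."""

    system: MolecularSystem
    times_ps: np.ndarray      # (f,)
    coords: np.ndarray        # (f, n, 3) nm
    boxes: np.ndarray | None = None   # (f, 6): 3 lengths (nm) + 3 angles (deg)

    def __post_init__(self) -> None:
        if len(self.times_ps) == 0:
            raise EmptyInputError("trajectory has no frames")
        if self.coords.shape[1] != self.system.n_atoms:
            raise TopologyError(
                f"frame atom count {self.coords.shape[1]} != "
                f"topology atom count {self.system.n_atoms}"
            )
        if np.any(np.diff(self.times_ps) <= 0):
            raise FormatError("frame times must be strictly increasing")
        if self.boxes is not None and np.any(self.boxes[:, :3] <= 0):
            raise FormatError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times_ps)


@dataclass(frozen=True)
class SelectionSpec:
    """Named residue-range (or explicit residue list) selection."""

    name: str
    residue_range: tuple[int, int] | None = None   # inclusive, 1-based
    residues: tuple[int, ...] | None = None
    atom_filter: str = "all"   # all | heavy | backbone | c_alpha | n_and_o

    VALID_FILTERS = ("all", "heavy", "backbone", "c_alpha", "n_and_o")

    def __post_init__(self) -> None:
        if self.atom_filter not in self.VALID_FILTERS:
            raise SelectionError(
                f"selection '{self.name}': unknown atom_filter "
                f"{self.atom_filter!r}; expected one of {self.VALID_FILTERS}"
            )
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise SelectionError(
                    f"selection '{self.name}': range start {lo} > end {hi}"
                )

    def residue_set(self) -> set[int] | None:
        if self.residues is not None:
            return set(self.residues)
        if self.residue_range is not None:
            lo, hi = self.residue_range
            return set(range(lo, hi + 1))
        return None


BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "H", "HN", "OXT"})

#: default trigger-factor domain map; child ranges nest within parents
DEFAULT_TF_DOMAINS: dict[str, tuple[int, int]] = {
    "N-terminal": (1, 149),
    "N-core": (1, 111),
    "Linker": (112, 149),
    "PPIase": (150, 245),
    "C-terminal": (246, 432),
    "HA1-linker": (246, 302),
    "Arm1": (303, 359),
    "Arm2": (360, 415),
}

#: top-level domains that must tile the full chain
TF_TOP_LEVEL = ("N-terminal", "PPIase", "C-terminal")

#: default substrate truncate ranges (MBP numbering). The P2 start residue
#: is quoted inconsistently in the literature (112 vs 113); 112 is the
#: default here and the range is configurable wherever it is consumed.
SUBSTRATE_RANGES: dict[str, tuple[int, int]] = {
    "P1": (7, 62),
    "P2": (112, 248),
}
P2_ALTERNATE_RANGE = (113, 248)


@dataclass(frozen=True)
class DomainMap:
    """Named inclusive residue ranges, optionally nested."""

    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TF_DOMAINS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo > hi or lo <= 0:
                raise SelectionError(f"domain '{name}': bad range ({lo}, {hi})")

    def selection(self, name: str, atom_filter: str = "heavy") -> SelectionSpec:
        return SelectionSpec(
            name=name, residue_range=self.ranges[name], atom_filter=atom_filter
        )

    def items(self):
        return self.ranges.items()


# ---------------------------------------------------------------------------
# element inference


def infer_element(atom_name: str, element_field: str = "") -> str:
    """Classify an atom as C/N/O/S/H/other.

    Uses the PDB element column when present, else the first alphabetic
    character of the atom name (ambiguous names are logged).
    """
    e = element_field.strip().capitalize()
    if e in KNOWN_ELEMENTS:
        return e
    if e and e not in KNOWN_ELEMENTS:
        return "other"
    for ch in atom_name:
        if ch.isalpha():
            guess = ch.upper()
            if guess in KNOWN_ELEMENTS:
                if len(atom_name.strip()) > 1 and guess in ("C", "N", "O", "S"):
                    logger.debug("element for %r inferred as %s", atom_name, guess)
                return guess
            logger.debug("ambiguous atom name %r -> element 'other'", atom_name)
            return "other"
    return "other"


# ---------------------------------------------------------------------------
# PDB


def _parse_pdb_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable PDB ATOM record at line {lineno}") from exc
    element_field = line[76:78] if len(line) >= 78 else ""
    element = infer_element(name, element_field)
    return serial, name, element, resseq, resname, chain, (x, y, z)


def _read_pdb_models(path: Path, include_het: bool):
    """Return list of per-model atom-record lists."""
    models: list[list] = []
    current: list = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model and current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if rec == "HETATM" and not include_het:
                    continue
                parsed = _parse_pdb_atom_line(line, lineno)
                resname = parsed[4]
                if not include_het and (
                    resname in WATER_NAMES or resname in ION_NAMES
                ):
                    continue
                current.append(parsed)
    if current:
        models.append(current)
    return [m for m in models if m]


def _records_to_system(records) -> MolecularSystem:
    if not records:
        raise EmptyInputError("no atoms parsed from file")
    serials, names, elements, resseqs, resnames, chains, xyz = zip(*records)
    coords = np.asarray(xyz, dtype=float) / 10.0   # A -> nm
    return MolecularSystem(
        atom_ids=np.asarray(serials, dtype=int),
        atom_names=tuple(names),
        elements=tuple(elements),
        residue_indices=np.asarray(resseqs, dtype=int),
        residue_names=tuple(resnames),
        chain_ids=tuple(chains),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# GRO


def _read_gro(path: Path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"GRO file {path} too short")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise FormatError(f"bad atom count on line 2 of {path}") from exc
    if len(lines) < 2 + n_atoms + 1:
        raise FormatError(f"GRO file {path} truncated")
    records = []
    for i, line in enumerate(lines[2 : 2 + n_atoms], start=3):
        try:
            resseq = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"unparseable GRO atom record at line {i}") from exc
        records.append(
            (serial, name, infer_element(name), resseq, resname, "A", (x, y, z))
        )
    return records


def load_structure(path, format: str | None = None, include_het: bool = False) -> MolecularSystem:
    """Load a PDB or GRO file as a MolecularSystem (coordinates in nm).

    Water, ions and heteroatoms are dropped unless ``include_het``.
    The format is inferred from the suffix when not given.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    logger.info("loading structure %s (format=%s)", path, fmt)
    if fmt == "pdb":
        models = _read_pdb_models(path, include_het)
        if not models:
            raise EmptyInputError(f"no atoms in {path}")
        system = _records_to_system(models[0])
    elif fmt == "gro":
        records = _read_gro(path)
        # GRO coordinates are already nm; undo the A->nm division
        system = _records_to_system(records)
        system = replace(system, coords=system.coords * 10.0)
    else:
        raise FormatError(f"unknown structure format {fmt!r}")
    return system


def write_structure(system: MolecularSystem, path, format: str | None = None) -> None:
    """Write PDB (nm -> Angstrom) or GRO (nm) for round-trips and fixtures."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        with open(path, "w") as fh:
            fh.write(_format_pdb_frame(system, system.coords))
            fh.write("END\n")
    elif fmt == "gro":
        with open(path, "w") as fh:
            fh.write("written by chaptraj\n")
            fh.write(f"{system.n_atoms:5d}\n")
            for i in range(system.n_atoms):
                x, y, z = system.coords[i]
                fh.write(
                    f"{int(system.residue_indices[i]) % 100000:5d}"
                    f"{system.residue_names[i]:<5s}{system.atom_names[i]:>5s}"
                    f"{int(system.atom_ids[i]) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write("   0.000   0.000   0.000\n")
    else:
        raise FormatError(f"unknown structure format {fmt!r}")


def _format_pdb_frame(system: MolecularSystem, coords_nm: np.ndarray) -> str:
    out = []
    for i in range(system.n_atoms):
        x, y, z = coords_nm[i] * 10.0
        name = system.atom_names[i]
        pad = f" {name:<3s}" if len(name) < 4 else name[:4]
        out.append(
            f"ATOM  {int(system.atom_ids[i]) % 100000:5d} {pad} "
            f"{system.residue_names[i]:<3s} {system.chain_ids[i][:1]}"
            f"{int(system.residue_indices[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{(system.elements[i] if system.elements[i] != 'other' else ''):>2s}\n"
        )
    return "".join(out)


# ---------------------------------------------------------------------------
# trajectories


def load_trajectory(
    path,
    topology: MolecularSystem,
    format: str | None = None,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Load a trajectory against a topology.

    Multi-model PDB is parsed natively. XTC/TRR/DCD are delegated to
    MDAnalysis when it is installed. When the format stores no times,
    they are synthesized as ``frame_index * dt_ps``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    logger.info("loading trajectory %s (format=%s)", path, fmt)
    if fmt == "pdb":
        models = _read_pdb_models(path, include_het=False)
        if not models:
            raise EmptyInputError(f"no frames in {path}")
        frames = []
        for m in models:
            if len(m) != topology.n_atoms:
                raise TopologyError(
                    f"frame atom count {len(m)} != topology {topology.n_atoms}"
                )
            frames.append(np.asarray([r[6] for r in m], dtype=float) / 10.0)
        coords = np.stack(frames)
        times = np.arange(len(frames), dtype=float) * dt_ps
        return Trajectory(system=topology, times_ps=times, coords=coords)
    if fmt in ("xtc", "trr", "dcd"):
        return _load_binary_trajectory(path, topology, dt_ps)
    raise FormatError(f"unknown trajectory format {fmt!r}")


def _load_binary_trajectory(path: Path, topology: MolecularSystem, dt_ps: float) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:   # pragma: no cover
        raise FormatError(
            "MDAnalysis is required for XTC/TRR/DCD trajectories"
        ) from exc
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        u.load_new(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read trajectory {path}: {exc}") from exc
    frames, times, boxes = [], [], []
    has_box = True
    for ts in u.trajectory:
        if ts.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"frame atom count {ts.n_atoms} != topology {topology.n_atoms}"
            )
        frames.append(ts.positions.astype(float) / 10.0)   # A -> nm
        times.append(float(ts.time))
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            has_box = False
        else:
            dims = np.array(ts.dimensions, dtype=float)
            dims[:3] /= 10.0
            boxes.append(dims)
    if not frames:
        raise EmptyInputError(f"no frames in {path}")
    times = np.asarray(times)
    if np.any(np.diff(times) <= 0):
        times = np.arange(len(frames), dtype=float) * dt_ps
    return Trajectory(
        system=topology,
        times_ps=times,
        coords=np.stack(frames),
        boxes=np.stack(boxes) if has_box and boxes else None,
    )


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:8d}\n")
            fh.write(_format_pdb_frame(traj.system, traj.coords[f]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# selections


def resolve_selection(system: MolecularSystem, spec: SelectionSpec) -> np.ndarray:
    """Resolve a SelectionSpec to a sorted, duplicate-free atom index array."""
    mask = np.ones(system.n_atoms, dtype=bool)
    residues = spec.residue_set()
    if residues is not None:
        mask &= np.isin(system.residue_indices, sorted(residues))
    if spec.atom_filter == "heavy":
        mask &= np.array([e != "H" for e in system.elements])
    elif spec.atom_filter == "backbone":
        mask &= np.array(
            [n in BACKBONE_NAMES for n in system.atom_names]
        )
    elif spec.atom_filter == "c_alpha":
        mask &= np.array([n == "CA" for n in system.atom_names])
    elif spec.atom_filter == "n_and_o":
        mask &= np.array([e in ("N", "O") for e in system.elements])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection '{spec.name}' resolved to zero atoms")
    logger.info("selection '%s' -> %d atoms", spec.name, idx.size)
    return idx


def iter_residue_atom_indices(
    system: MolecularSystem, spec: SelectionSpec
) -> Iterable[tuple[int, np.ndarray]]:
    """Yield (residue_index, atom indices) for each residue in a selection."""
    all_idx = resolve_selection(system, spec)
    resids = system.residue_indices[all_idx]
    for r in np.unique(resids):
        yield int(r), all_idx[resids == r]
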