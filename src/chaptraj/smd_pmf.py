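"""Steered-pulling work curves and free-energy (PMF) estimation.

Work is accumulated against the moving spring anchor; the extension
coordinate is the anchor displacement from its start (nominal pull speed
times elapsed time). Free-energy profiles come from the Jarzynski
exponential average (with log-sum-exp stabilization) and from the
second-cumulant stiff-spring approximation, together with the reliability
span over which the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from chaptraj.errors import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    RangeError,
)

#: kB in kJ/mol/K; beta at 300 K in mol/kJ
KB_KJ_PER_MOL_K = 0.0083144621
BETA_300K = 1.0 / (KB_KJ_PER_MOL_K * 300.0)


@dataclass(frozen=True)
class PullTrace:
    """One steered-pulling record.

    ``spring_constant`` is in kJ/mol/nm^2 (units must be supplied
    explicitly by callers converting from other conventions).
    """

    times_ps: np.ndarray
    coordinate_nm: np.ndarray       # instantaneous pulled coordinate
    anchor_nm: np.ndarray           # moving anchor position
    spring_constant: float | None = None
    pull_speed_nm_per_ns: float | None = None
    force_kj_mol_nm: np.ndarray | None = None   # optional recorded spring force

    def __post_init__(self) -> None:
        n = len(self.times_ps)
        if len(self.coordinate_nm) != n or len(self.anchor_nm) != n:
            raise ValueError("trace columns must share one length")
        if self.spring_constant is not None and self.spring_constant <= 0:
            raise ParameterError("spring constant must be positive")

    @property
    def extension_nm(self) -> np.ndarray:
        """Anchor displacement from its starting position."""
        return self.anchor_nm - self.anchor_nm[0]


@dataclass(frozen=True)
class WorkCurve:
    extension_nm: np.ndarray    # strictly increasing, starts at 0
    work_kj_mol: np.ndarray     # W(0) = 0

    def __post_init__(self) -> None:
        if len(self.extension_nm) != len(self.work_kj_mol):
            raise ValueError("grid/work length mismatch")
        if abs(self.work_kj_mol[0]) > 1e-12:
            raise ValueError("work must start at zero")
        if np.any(np.diff(self.extension_nm) <= 0):
            raise ValueError("extension grid must be strictly increasing")


@dataclass(frozen=True)
class PMFEstimate:
    extension_nm: np.ndarray
    jarzynski_kj_mol: np.ndarray
    cumulant_kj_mol: np.ndarray
    mean_work_kj_mol: np.ndarray
    beta: float
    n_curves: int
    reliable_span_nm: tuple[float, float] | None


def work_curve(trace: PullTrace) -> WorkCurve:
    """Cumulative work against the anchor: W(t) = int v * f_spring dt.

    The spring force on the pulled coordinate is k*(anchor - coordinate)
    unless an explicit force column was recorded. Trapezoidal integration
    over time; the abscissa is the anchor displacement.
    """
    ext = trace.extension_nm
    if np.any(np.diff(trace.anchor_nm) < 0):
        raise FormatError("anchor motion must be monotone non-decreasing")
    if np.any(np.diff(ext) <= 0):
        raise FormatError("anchor must advance strictly between samples")
    if trace.force_kj_mol_nm is not None:
        force = np.asarray(trace.force_kj_mol_nm, dtype=float)
    elif trace.spring_constant is not None:
        force = trace.spring_constant * (trace.anchor_nm - trace.coordinate_nm)
    else:
        raise FormatError(
            "trace has neither a force column nor a spring constant"
        )
    if trace.pull_speed_nm_per_ns is not None:
        v = trace.pull_speed_nm_per_ns / 1000.0   # nm/ps
        integrand = v * force
        work = np.concatenate(
            ([0.0], np.cumsum(
                0.5 * (integrand[1:] + integrand[:-1]) * np.diff(trace.times_ps)
            ))
        )
    else:
        # v dt = d(anchor); integrate force over anchor displacement
        work = np.concatenate(
            ([0.0], np.cumsum(0.5 * (force[1:] + force[:-1]) * np.diff(ext)))
        )
    return WorkCurve(extension_nm=ext, work_kj_mol=work)


def resample_to_grid(curves: list[WorkCurve], grid: np.ndarray) -> np.ndarray:
    """Linearly interpolate each curve onto a shared extension grid.

    Returns an (n_curves, n_grid) work array. Grid points must lie within
    every curve's extension span.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.empty((len(curves), len(grid)))
    for i, c in enumerate(curves):
        if grid[0] < c.extension_nm[0] - 1e-12 or grid[-1] > c.extension_nm[-1] + 1e-12:
            raise RangeError(
                f"grid [{grid[0]}, {grid[-1]}] outside curve span "
                f"[{c.extension_nm[0]}, {c.extension_nm[-1]}]"
            )
        out[i] = np.interp(grid, c.extension_nm, c.work_kj_mol)
    return out


def jarzynski_pmf(work: np.ndarray, beta: float = BETA_300K) -> np.ndarray:
    """PMF(s) = -(1/beta) ln mean_i exp(-beta W_i(s)), log-sum-exp stabilized."""
    if beta <= 0:
        raise ParameterError("beta must be positive")
    work = np.atleast_2d(work)
    n = work.shape[0]
    return -(logsumexp(-beta * work, axis=0) - np.log(n)) / beta


def cumulant_pmf(work: np.ndarray, beta: float = BETA_300K) -> np.ndarray:
    """Stiff-spring second-cumulant PMF: <W> - (beta/2) Var(W), unbiased."""
    work = np.atleast_2d(work)
    if work.shape[0] < 2:
        raise DegenerateInputError("cumulant estimator needs >= 2 curves")
    mean = work.mean(axis=0)
    var = work.var(axis=0, ddof=1)
    return mean - 0.5 * beta * var


def mean_work(work: np.ndarray) -> np.ndarray:
    return np.atleast_2d(work).mean(axis=0)


def pmf_reliability(
    grid: np.ndarray,
    jarzynski: np.ndarray,
    cumulant: np.ndarray,
    tol_kj_mol: float,
) -> tuple[float, float] | None:
    """Maximal initial contiguous span where |jarzynski - cumulant| < tol."""
    ok = np.abs(jarzynski - cumulant) < tol_kj_mol
    if not ok[0]:
        return None
    end = len(ok) if ok.all() else int(np.argmin(ok))
    return float(grid[0]), float(grid[end - 1])


def barrier_height(
    grid: np.ndarray, profile: np.ndarray, window: tuple[float, float]
) -> float:
    """max(profile) - profile(window start), within the window."""
    lo, hi = window
    mask = (grid >= lo) & (grid <= hi)
    if not mask.any():
        raise RangeError(f"window ({lo}, {hi}) contains no grid points")
    sub = profile[mask]
    return float(sub.max() - sub[0])


def estimate_pmf(
    curves: list[WorkCurve],
    grid: np.ndarray,
    beta: float = BETA_300K,
    reliability_tol_kj_mol: float = 2.5,
) -> PMFEstimate:
    """Full pipeline: resample, Jarzynski + cumulant profiles, reliability."""
    grid = np.asarray(grid, dtype=float)
    work = resample_to_grid(curves, grid)
    jar = jarzynski_pmf(work, beta)
    mean = mean_work(work)
    if work.shape[0] >= 2:
        cum = cumulant_pmf(work, beta)
        span = pmf_reliability(grid, jar, cum, reliability_tol_kj_mol)
    else:
        cum = mean.copy()
        span = None
    return PMFEstimate(
        extension_nm=grid,
        jarzynski_kj_mol=jar,
        cumulant_kj_mol=cum,
        mean_work_kj_mol=mean,
        beta=beta,
        n_curves=work.shape[0],
        reliable_span_nm=span,
    )


# ---------------------------------------------------------------------------
# trace files


def read_pull_trace(
    path,
    spring_constant: float | None = None,
    pull_speed_nm_per_ns: float | None = None,
) -> PullTrace:
    """Read a whitespace-separated pulling trace.

    Supports the COLVAR dialect (header ``#! FIELDS time <names...>``) and
    plain TSV with a ``#``-prefixed header naming at least ``time`` plus
    ``position``/``coordinate`` and ``anchor`` (optionally ``force``).
    """
    path = Path(path)
    names: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#! FIELDS"):
                names = line.split()[2:]
                continue
            if line.startswith("#"):
                fields = line.lstrip("#").split()
                if "time" in fields:
                    names = fields
                continue
            rows.append([float(v) for v in line.split()])
    if not rows:
        raise FormatError(f"no data rows in {path}")
    data = np.asarray(rows)
    if names is None:
        if data.shape[1] < 3:
            raise FormatError(
                f"{path}: headerless trace needs >= 3 columns (time, coord, anchor)"
            )
        names = ["time", "coordinate", "anchor"] + [
            f"col{i}" for i in range(3, data.shape[1])
        ]
    cols = {n: data[:, i] for i, n in enumerate(names)}
    coord_key = next(
        (k for k in ("coordinate", "position", "distance", "cv") if k in cols), None
    )
    if "time" not in cols or coord_key is None or "anchor" not in cols:
        raise FormatError(
            f"{path}: trace must name time, coordinate/position and anchor columns"
        )
    return PullTrace(
        times_ps=cols["time"],
        coordinate_nm=cols[coord_key],
        anchor_nm=cols["anchor"],
        spring_constant=spring_constant,
        pull_speed_nm_per_ns=pull_speed_nm_per_ns,
        force_kj_mol_nm=cols.get("force"),
    )


def write_pull_trace(trace: PullTrace, path) -> None:
    cols = ["time", "coordinate", "anchor"]
    arrays = [trace.times_ps, trace.coordinate_nm, trace.anchor_nm]
    if trace.force_kj_mol_nm is not None:
        cols.append("force")
        arrays.append(trace.force_kj_mol_nm)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for row in zip(*arrays):
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
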