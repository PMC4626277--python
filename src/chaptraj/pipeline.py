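"""Config-driven orchestration of the analysis stages.

A YAML config declares inputs (structures, multi-model PDB trajectories,
distance-trace TSVs, pulling traces), selections, thresholds, strand pairs
and PMF settings; ``run_pipeline`` executes every declared stage in
dependency order and writes a TSV/JSON report bundle. Failure of one
system's analysis is recorded and does not abort the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from chaptraj import contact_kinetics, md_io, pf_hbonds, smd_pmf
from chaptraj.errors import ChaptrajError, ConfigurationError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def _version() -> str:
    from chaptraj import __version__

    return __version__


@dataclass
class Finding:
    severity: str   # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.message}"


@dataclass
class AnalysisConfig:
    raw: dict
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw=raw, path=path)

    @property
    def thresholds(self) -> dict:
        t = dict(self.raw.get("thresholds", {}))
        t.setdefault("attach_nm", contact_kinetics.ATTACH_NM)
        t.setdefault("detach_nm", contact_kinetics.DETACH_NM)
        t.setdefault("contact_nm", contact_kinetics.CONTACT_NM)
        return t

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: AnalysisConfig) -> list[Finding]:
    """Return ALL problems found, never just the first."""
    findings: list[Finding] = []
    raw = config.raw
    base = config.path.parent if config.path else Path(".")
    t = config.thresholds
    if t["attach_nm"] >= t["detach_nm"]:
        findings.append(
            Finding(
                "error",
                f"attach threshold {t['attach_nm']} must be < detach "
                f"threshold {t['detach_nm']}",
            )
        )
    has_stage = False
    for key in ("distance_traces", "pull_traces", "trajectories"):
        entries = raw.get(key, [])
        if entries:
            has_stage = True
        for entry in entries:
            p = entry["path"] if isinstance(entry, dict) else entry
            if not (base / p).exists():
                findings.append(Finding("error", f"{key}: missing file {p}"))
    if raw.get("structure") and not (base / raw["structure"]).exists():
        findings.append(
            Finding("error", f"structure: missing file {raw['structure']}")
        )
    if raw.get("trajectories") and not raw.get("structure"):
        findings.append(
            Finding("error", "trajectories declared but no structure/topology")
        )
    for name, rng in raw.get("domains", {}).items():
        if not (isinstance(rng, (list, tuple)) and len(rng) == 2 and rng[0] <= rng[1]):
            findings.append(Finding("error", f"domain {name}: bad range {rng}"))
    if not has_stage:
        findings.append(
            Finding("error", "config declares no analyzable inputs")
        )
    return findings


def _load_distance_trace(path: Path) -> contact_kinetics.DistanceSeries:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected columns time_ps distance_nm")
    return contact_kinetics.DistanceSeries(
        times_ps=data[:, 0], values_nm=data[:, 1]
    )


def run_pipeline(config: AnalysisConfig, out_dir) -> dict:
    """Execute every declared stage; return (and write) the run report."""
    findings = validate_config(config)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ConfigurationError(
            "config validation failed:\n" + "\n".join(str(f) for f in errors)
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = config.path.parent if config.path else Path(".")
    raw = config.raw
    t = config.thresholds
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "chaptraj_version": _version(),
            "config_hash": config.config_hash(),
            "seed": raw.get("seed"),
            "thresholds": t,
        },
        "failures": [],
    }

    # --- binding kinetics from distance traces -------------------------------
    traces = raw.get("distance_traces", [])
    if traces:
        event_lists = []
        lengths_ns = []
        rows = []
        for entry in traces:
            p = entry["path"] if isinstance(entry, dict) else entry
            try:
                series = _load_distance_trace(base / p)
                events = contact_kinetics.detect_events(
                    series, t["attach_nm"], t["detach_nm"]
                )
                event_lists.append(events)
                lengths_ns.append(float(series.times_ps[-1]) / 1000.0)
                for e in events:
                    rows.append((p, e.kind, e.time_ps, e.frame_index))
            except (ChaptrajError, OSError, ValueError) as exc:
                report["failures"].append({"input": str(p), "error": str(exc)})
                logger.error("distance trace %s failed: %s", p, exc)
        _write_tsv(
            out_dir / "events.tsv",
            ("trajectory_id", "kind", "time_ps", "frame"),
            rows,
            params=t,
        )
        kin = contact_kinetics.binding_kinetics(event_lists, lengths_ns)
        report["kinetics"] = {
            "tau_ns": kin.tau_ns,
            "n_events": kin.n_events,
            "n_trajectories": len(event_lists),
            "n_unbound": kin.n_unbound,
            "first_binding_times_ns": list(kin.first_binding_times_ns),
        }

    # --- PF-contact distributions over a trajectory --------------------------
    if raw.get("structure") and raw.get("trajectories"):
        system = md_io.load_structure(base / raw["structure"])
        criterion = pf_hbonds.HBondCriterion(
            donor_acceptor_max_nm=raw.get("hbond", {}).get("dmax_nm", 0.35),
            angle_max_deg=raw.get("hbond", {}).get("amax_deg", 30.0),
            heavy_only_fallback=raw.get("hbond", {}).get("heavy_only", False),
        )
        pairs = [pf_hbonds.StrandPair.parse(s) for s in raw.get("strand_pairs", [])]
        pf_rows = []
        for entry in raw["trajectories"]:
            p = entry["path"] if isinstance(entry, dict) else entry
            try:
                traj = md_io.load_trajectory(base / p, system)
                if pairs:
                    for s in pf_hbonds.pf_contact_series(traj, pairs, criterion):
                        for f, c in enumerate(s.counts):
                            pf_rows.append((p, s.pair.label, f, int(c)))
            except (ChaptrajError, OSError) as exc:
                report["failures"].append({"input": str(p), "error": str(exc)})
                logger.error("trajectory %s failed: %s", p, exc)
        if pairs:
            _write_tsv(
                out_dir / "pf_contacts.tsv",
                ("trajectory_id", "pair", "frame", "n_bonds"),
                pf_rows,
            )
            report["pf_contacts"] = {"n_rows": len(pf_rows)}

    # --- PMF from pulling traces ---------------------------------------------
    pulls = raw.get("pull_traces", [])
    if pulls:
        pmf_cfg = raw.get("pmf", {})
        beta = float(pmf_cfg.get("beta", smd_pmf.BETA_300K))
        spring_k = pmf_cfg.get("spring_constant")
        speed = pmf_cfg.get("pull_speed_nm_per_ns")
        curves = []
        for entry in pulls:
            p = entry["path"] if isinstance(entry, dict) else entry
            try:
                trace = smd_pmf.read_pull_trace(
                    base / p, spring_constant=spring_k, pull_speed_nm_per_ns=speed
                )
                curves.append(smd_pmf.work_curve(trace))
            except (ChaptrajError, OSError, ValueError) as exc:
                report["failures"].append({"input": str(p), "error": str(exc)})
                logger.error("pull trace %s failed: %s", p, exc)
        if curves:
            span_max = min(float(c.extension_nm[-1]) for c in curves)
            g = pmf_cfg.get("grid")
            if g:
                grid = np.arange(g["start"], g["stop"] + 0.5 * g["step"], g["step"])
            else:
                grid = np.linspace(0.0, span_max, 101)
            est = smd_pmf.estimate_pmf(
                curves, grid, beta=beta,
                reliability_tol_kj_mol=pmf_cfg.get("reliability_tol", 2.5),
            )
            _write_tsv(
                out_dir / "pmf.tsv",
                ("extension_nm", "mean_work", "jarzynski", "cumulant"),
                zip(
                    est.extension_nm,
                    est.mean_work_kj_mol,
                    est.jarzynski_kj_mol,
                    est.cumulant_kj_mol,
                ),
                params={"beta": beta, "n_curves": est.n_curves},
            )
            barrier = None
            if est.reliable_span_nm is not None:
                barrier = smd_pmf.barrier_height(
                    est.extension_nm, est.cumulant_kj_mol, est.reliable_span_nm
                )
            report["pmf"] = {
                "n_curves": est.n_curves,
                "beta": beta,
                "reliable_span_nm": est.reliable_span_nm,
                "barrier_kj_mol": barrier,
            }

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_tsv(path: Path, header, rows, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        if params:
            for k in sorted(params):
                fh.write(f"# {k} = {params[k]}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float) or isinstance(v, np.floating):
        return f"{float(v):.10g}"
    return str(v)
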