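# chaptraj

Trajectory analysis for chaperone–substrate binding studies: inter-molecular
contact kinetics with two-threshold (hysteresis) event detection, ensemble
binding statistics, per-residue contact-probability maps, β-sheet backbone
hydrogen-bond ("PF-contact") counting, conformational metrics (Rg, COM
distance, RMSF, SASA, native-contact fraction), dihedral PCA, and
free-energy profiles from steered-pulling work curves via the Jarzynski and
second-cumulant estimators. A synthetic-data module generates inputs with
exactly known ground truth (two-state binding traces, overdamped Langevin
pulling ensembles on analytic potentials, idealized β-strand geometries,
dihedral ensembles), so every stage is testable offline.

## Conventions

- Internal length unit is **nm**; PDB input (Å) is converted on load.
- Residue numbering is 1-based, taken verbatim from the input file; ranges
  are inclusive.
- Event detection starts in the unbound state; attachment fires strictly
  below the attach threshold (default 0.4 nm), detachment strictly above
  the detach threshold (default 1.0 nm); values in between never switch
  state.
- The binding-summary event count `n_events` counts completed
  attachment→detachment cycles (i.e. detachments). The mean first binding
  time averages, over trajectories that end bound, the time of the last
  attachment not followed by any detachment; trajectories ending unbound
  are reported separately, never imputed.
- Work is accumulated against the moving spring anchor; the extension
  coordinate is the anchor displacement (pull speed × time). Default
  β corresponds to 300 K in kJ/mol units (β ≈ 0.4009 mol/kJ).

## CLI

```sh
chaptraj contacts --top complex.pdb --traj traj.pdb \
    --sel-a 1-432 --sel-b 433-488 --attach 0.4 --detach 1.0 --out events.tsv
chaptraj pf  --top p1.pdb --traj p1_traj.pdb --pairs 7-11:58-62,7-11:35-39 --out pf.tsv
chaptraj pmf --traces pulls/ --spring-k 1000 --grid 0:0.7:0.005 --out pmf.tsv
chaptraj rg / rmsf / sasa / qnative ...
chaptraj synth binding|smd|hairpin|dihedrals --seed 1 --out dir/
chaptraj run config.yaml --out report/
```

`chaptraj run` consumes a YAML config (keys: `structure`, `trajectories`,
`distance_traces`, `pull_traces`, `selections`, `domains`, `thresholds`
{attach_nm, detach_nm}, `strand_pairs`, `pmf` {beta, grid,
spring_constant}, `seed`) and writes a TSV/JSON report bundle;
`chaptraj validate config.yaml` reports every config problem at once.

## Layout

| module | contents |
| --- | --- |
| `chaptraj.md_io` | PDB/GRO structures, trajectories, selections, domain maps |
| `chaptraj.contact_kinetics` | min-distance series, hysteresis events, binding stats, contact probability, hydrophilic fraction |
| `chaptraj.structure_metrics` | Rg, COM distance, RMSF, Shrake–Rupley SASA, native-contact fraction |
| `chaptraj.pf_hbonds` | backbone H-bonds between strand pairs, PF-contact series |
| `chaptraj.dihedral_pca` | φ/ψ torsions, sin/cos-transformed PCA |
| `chaptraj.smd_pmf` | work curves, Jarzynski/cumulant PMF, reliability span, barrier heights |
| `chaptraj.synthetic_data` | seeded ground-truth generators |
| `chaptraj.pipeline` / `chaptraj.cli` | config-driven orchestration and the `chaptraj` command |
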