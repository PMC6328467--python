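# gsecdyn

Trajectory analysis of γ-secretase dynamics: superposition/RMSD machinery,
principal component analysis of collective motions, helix and domain
tilt-angle ensembles, active-site state segmentation, cavity hydration
mapping and lipid-immobilization scoring — together with a
synthetic-trajectory generator that plants known ground truth for every
analysis stage.

## The scientific problem

γ-secretase is the four-subunit intramembrane aspartyl protease (nicastrin,
presenilin-1, APH-1a, PEN-2) that cleaves single-span transmembrane
substrates such as the amyloid precursor protein's C99 fragment.  Its
catalytic aspartates, D257 (TMD 6) and D385 (TMD 7) of presenilin-1, must
come into close proximity — with water present deep inside the bilayer —
before hydrolysis can occur.  Microsecond molecular-dynamics studies of the
complex characterize this activation through a recurring set of trajectory
analyses:

* **Superposition and RMSD** — optimal least-squares (Kabsch) fits, Cα RMSD
  traces against a reference frame, per-residue RMSD heatmaps vs a state
  mean, and the cross-trajectory *noise-subtracted* heatmap
  `|RMSD_cross − RMSD_self|` that isolates deviations beyond a system's own
  fluctuations.
* **Collective motions** — PCA of the Cα positional covariance after
  alignment: eigenvalues λ₁ ≥ λ₂ ≥ …, cumulative variance fractions
  f_k = Σ_{i≤k} λ_i / Σ_i λ_i, per-frame mode projections and mode-extreme
  structures for visualization.
* **Tilt angles** — the angle θ between a helix axis (principal axis of its
  Cα cloud) or a domain COM axis and the membrane normal (+z), after a
  common fit on PS1 TMDs 4, 5, 7, 8, 9; the ensemble spread is the sample
  standard deviation of θ.
* **State segmentation** — a single least-squares changepoint on the
  running-averaged D257–D385 distance series splits the trajectory into
  inactive (far aspartates) and active (close) states, with per-state
  statistics, hydrogen-bond and water-bridge frame classification.
* **Hydration** — per-frame counts of water oxygens in protein-anchored
  boxes, bulk-relative z-density profiles, and dual-proximity counts near
  both catalytic carboxylates.
* **Lipid immobilization** — heavy-atom B-factors
  `B = (8π²/3)·⟨|r − ⟨r⟩|²⟩` of lipid chains on the protein-aligned,
  periodically unwrapped trajectory; persistently low-B chains mark putative
  substrate-binding exosites, assigned by their protein-segment contact
  sets.

The package is for structural bioinformaticians who want these operators as
tested, composable library functions (plus a thin CLI) rather than
one-off analysis scripts — and who need a way to validate them without
access to the original trajectories: the `synthetic_data` module generates
desk-scale stand-in systems whose planted statistics mirror the published
study conditions (inactive/active Cα–Cα distances 9.1 ± 0.6 / 8.3 ± 0.6 Å,
a transition at frame 1750 of 3500, binding-region water counts 34.8 with
σ 4.4 → 3.0, dual-proximity water means 1.0 → 2.6, tilt wobble of ~2°,
trapped vs freely diffusing lipids).

## Worked example

```python
import gsecdyn as g
from gsecdyn.synthetic_data import SyntheticSpec, TransitionSpec, generate

spec = SyntheticSpec(n_frames=1000, transition=TransitionSpec(frame=500))
system, traj, truth = generate(spec, seed=42)

a = g.residue_site(system, "PS1", 257, "CA")
b = g.residue_site(system, "PS1", 385, "CA")
d = g.distance_series(traj, a, b, label="dCA")
seg = g.segment_states(d, buffer=50, window=100)
print(f"transition frame: {seg.transition_frame}")
for state in ("inactive", "active"):
    s = seg.per_state["dCA"][state]
    print(f"{state:>8}: d(D257-D385) = {s['mean']:.2f} +/- {s['std']:.2f} A  (n={s['n']})")

waters = g.select(system, "WATER and name O")
sa = g.residue_site(system, "PS1", 257, "sidechain")
sb = g.residue_site(system, "PS1", 385, "sidechain")
_, per_state = g.dual_proximity_waters(traj, sa, sb, waters, 4.0, seg)
print("catalytic waters (<=4 A of both): "
      f"{per_state['inactive']:.1f} -> {per_state['active']:.1f}")
```

Output:

```
transition frame: 503
inactive: d(D257-D385) = 9.10 +/- 0.61 A  (n=453)
  active: d(D257-D385) = 8.31 +/- 0.62 A  (n=447)
catalytic waters (<=4 A of both): 1.0 -> 2.6
```

The changepoint lands three frames from the planted transition (500); the
per-state distance statistics and the jump in catalytically positioned
waters recover the planted study conditions.

The same analyses are available from the shell:

```bash
gsecdyn simulate --seed 1 --frames 500 --out run1     # PDB + DCD + truth JSON
gsecdyn states --synthetic-seed 1 --frames 500 --out run1
gsecdyn run config.yaml                               # full config-driven sweep
```

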