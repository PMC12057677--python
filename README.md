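# carbodyn

Trajectory analysis for the dissociation dynamics of aqueous carbonic acid.

Carbonic acid (H₂CO₃) — not water or CO₂ — is the working proton donor of
the CO₂/H₂CO₃/HCO₃⁻ buffer that regulates pH in blood and oceans.  In
solution it interconverts between three conformers, cis–cis (CC), cis–trans
(CT) and trans–trans (TT), defined by the two =O–C–O(H)–H dihedral angles
α and β (cis ≈ 0, trans ≈ π), and it dissociates by Grotthuss proton
hopping: the proton leaves a hydroxyl oxygen, relays through the water
hydrogen-bond network, and usually returns.  Resolving which conformer
donates protons, along which pathways, requires nanosecond reactive
trajectories and careful event detection — in particular the removal of
*rattling*, the rapid back-and-forth proton exchange between two oxygens
that constitutes no net transfer.

`carbodyn` is the analysis side of that problem, built for reactive MD
trajectories (XYZ / extended-XYZ / LAMMPS text dumps) of one acid molecule
in a periodic water box.  It provides:

- **Speciation and conformer tracking** — per-frame H→O assignment, carbon
  species (H₂CO₃ / HCO₃⁻ / CO₃²⁻), conformer labels from (α, β), and mole
  percents x_i = n_i/N.
- **Proton-transfer episodes** — defect tracking through the O network, a
  minimum-residence rattling filter (τ_commit = 0.2 ps), hop counting
  (dissociation and recombination inclusive, so the minimal episode has 2
  hops), and classification: short/long-range, single/concerted,
  homing/exploratory endpoints, direct vs indirect (via HCO₃⁻) conformer
  transitions, and proton-source fractions.
- **H-bond ring statistics** — geometric H-bonds (r(O···O) ≤ 3.5 Å, angle
  ≤ 30°), a molecule graph with the solute contracted to one node, and
  primitive-ring counts through the solute per conformer.
- **Histogram estimators** — periodic-boundary RDFs with peak picking, the
  smooth hydrogen coordination number n(O) = Σ_H (1−(r/r₀)⁶)/(1−(r/r₀)¹²),
  1D dissociation free-energy profiles F = −kT ln p̂ with a barrier
  read-off, and the 2D (α, β) free-energy surface.
- **Wannier-center analysis** — lone/bonding classification of precomputed
  maximally-localized Wannier-function centers and R(O–MLWF) distributions
  per oxygen role and conformer.
- **A synthetic generator** — seed-deterministic Markov state sequences,
  episode scripts and atomistic renderings with ground-truth logs, so every
  analysis stage is verifiable without running MD.

## Worked example

Generate a calibrated stream of 1000 dissociation episodes, render it to an
atomistic trajectory, and run the proton-transfer pipeline:

```python
from carbodyn.protons import analyze_protons
from carbodyn.synth import (generate_episode_stream, load_fixture,
                            render_atomistic)

fx = load_fixture("episodes_paper.yaml")          # calibrated generator config
scripts, truth = generate_episode_stream(fx, 1000, seed=11)
traj, log = render_atomistic(scripts, n_waters=fx["n_waters"],
                             box=fx["box_A"], seed=11, dt=fx["dt_ps"])
st = analyze_protons(traj).statistics
print("completed episodes:", st["n_completed"])
print("CT source fraction: %.1f%%" % st["source_fraction_pct"]["CT"])
print("homing CT: %.1f%%  homing CC: %.1f%%"
      % (st["homing_fraction_pct"]["CT"], st["homing_fraction_pct"]["CC"]))
print("short-range (2-hop): %.1f%%" % st["short_range_pct"])
```

prints

```
completed episodes: 1000
CT source fraction: 60.8%
homing CT: 82.4%  homing CC: 60.2%
short-range (2-hop): 63.4%
```

All 1000 scripted episodes are detected (rattle insertions included in the
rendering are removed by the residence filter).  The CT conformer supplies
60.8 % of the dissociated protons in this draw (generator weight 58.1 %),
and protons from CT return to the oxygen they left — the homing pathway —
more often (82.4 %) than protons from CC (60.2 %); the remainder land on
the original carbonyl oxygen (exploratory).  Most episodes are the two-hop
dissociate-and-return motif.  Sampling scatter around the generator
weights is binomial (≈ ±1.6 % at n = 1000).

The same library drives a small CLI (`carbodyn analyze|synth|rdf|rings|
protons|fes|wannier`) around a single YAML config; `carbodyn analyze -c
config.yaml` writes TSV tables plus a schema-validated `report.json`.

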