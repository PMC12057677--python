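# Methods

`carbodyn` analyzes reactive molecular-dynamics trajectories of a single
carbonic-acid molecule in water: speciation and conformer populations,
proton-transfer (Grotthuss hopping) episodes, hydrogen-bond ring statistics,
Wannier-center polarization distances, and histogram free-energy estimators.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Chemical topology

Molecular identity in a reactive trajectory cannot come from a fixed bond
table.  Every frame, each hydrogen is assigned to its minimum-image nearest
oxygen — the standard reactive-MD convention.  A hard O–H cutoff would leave
protons unassigned mid-hop, so none is applied; assignments beyond
`topology.oh_warn = 1.30 Å` are only flagged as stretched.  Exact ties
(within 1 nÅ) resolve to the lower oxygen index and are logged.

The three carboxyl oxygens are the oxygens within `topology.co_cut = 1.60 Å`
of the carbon; the cutoff covers C–OH (≈1.34 Å) and C=O (≈1.21 Å) with
margin while excluding solvent (>2.5 Å).  The carbon species follows from
the summed hydrogen count on those three oxygens: 2 → H₂CO₃, 1 → HCO₃⁻,
0 → CO₃²⁻.

Conformers of the intact acid are classified from the two dihedral angles
α, β of the (=O, C, O_OH, H) chains, the carbonyl oxygen being the carboxyl
oxygen hosting no hydrogen.  An angle is *cis* iff |angle| < π/2: the
free-energy basins sit at 0 and ±π, so the midpoint is the natural
separatrix and the boundary has measure zero.  cis+cis → CC, mixed → CT,
trans+trans → TT.  Bicarbonate carries no conformer label.  Dihedrals use
minimum-image bond vectors and the IUPAC sign convention; +π is folded onto
−π so angles live in [−π, π).

Mole percents are the raw per-frame census x_i = n_i/N × 100.  An optional
minimum-persistence smoothing window (`topology.smooth_frames`, default 1 =
off) is exposed because a per-frame census and an event-level census can
differ for noisy data; the raw census is the default and is what every
shipped statistic uses.

## Proton-transfer episodes

The dissociated proton is tracked as the protonic defect: the non-acid
oxygen carrying three hydrogens (the hydronium oxygen).  Tracking the
defect rather than one fixed hydrogen atom is deliberate — under Grotthuss
relay the chemical identity of the excess proton changes at every hop.

**Rattling filter.**  Host residencies shorter than
`proton.tau_commit = 0.2 ps` are candidate rattling.  The series of host
intervals is compressed by a deterministic minimum-residence rule: delete
the largest (leftmost on ties) contiguous block of interior sub-threshold
intervals whose two flanking hosts coincide, absorb its duration into the
merged flank, and iterate to a fixed point.  Sub-threshold stretches whose
flanks differ mediate a real host change and are retained (or collapsed to
a direct hop with `proton.collapse_mediated = true`; default false to keep
hop counts faithful).  The first and last intervals of a series are
terminal and never deleted.  The largest-block-first priority makes the
rule order-independent and empirically preserves monotonicity: raising
`tau_commit` never increases the accepted hop count.  0.2 ps is a typical
proton-rattling timescale; setting `tau_commit = 0` disables filtering so
transient recrossings (the sub-picosecond deprotonation–return events seen
in short Born–Oppenheimer runs) become countable.

**Hop convention.**  Dissociation and recombination each count as one hop,
so the minimal completed episode — proton to the nearest water and straight
back — has n_hops = 2 ("short-range"); anything longer is "long-range".

**Episodes.**  An episode opens at an accepted hop leaving an acid oxygen
and closes at the first accepted hop landing on any carboxyl oxygen of the
same carbon; its source conformer is the last intact-acid label before the
opening hop.  Endpoints: *homing* (landing oxygen = origin hydroxyl
oxygen), *exploratory* (another carboxyl oxygen), *escaped* (trajectory
ended first; excluded from endpoint fractions).  Episodes during which the
acid loses both protons are flagged overlapping and excluded from
single-proton statistics (double dissociation is trace-level, <0.01 mol %).
Consecutive dissociation stretches separated by an associated gap shorter
than `tau_commit` on the same oxygen are stitched before filtering, so a
sub-threshold recombination inside an episode is itself treated as
rattling.

**Concerted hops.**  Consecutive accepted hops closer than
`proton.tau_concert = 0.1 ps` sharing an intermediate oxygen form one
concerted group (transitively); all others are single.

**Transitions.**  Successive distinct conformer labels yield one transition
event; it is *indirect* when a bicarbonate (or carbonate) interval
separates the labels, *direct* otherwise.  The headline fraction is over
CT→CC transitions; CT→HCO₃⁻→CT excursions are not CT→CC transitions and do
not enter it.  Source fractions weight episodes, not hops; hop weighting is
available behind a flag.

## Hydrogen-bond network and rings

A hydrogen bond requires donor–acceptor r(O···O) ≤ `hbond.r_cut = 3.5 Å`
and H–O_d···O_a angle ≤ `hbond.ang_cut = 30°` — the standard liquid-water
criterion, consistent with the acid–water RDF first minimum.  Bonds build
an undirected molecule graph; the whole solute contracts to one node, so
ring sizes count molecules (an atomic-oxygen mode is available for
sensitivity checks with `rings.contract_solute = false`).  Parallel bonds
between the same molecule pair collapse to one edge with a multiplicity
attribute — the TT "dual H-bond" motif (both hydroxyls bonded to one water)
is therefore an edge of multiplicity 2, not a ring.

Rings through the solute are *primitive* cycles up to
`rings.max_size = 8`: a cycle counts only if no pair of its nodes is joined
by a graph path shorter than the shorter arc along the cycle.  Cycle
enumeration uses networkx's bounded simple-cycle search; primitivity is
checked against BFS shortest paths.  Per-frame counts are averaged within
frames sharing each conformer label.

## Observables

**RDF.**  g(r) is the minimum-image pair histogram normalized by the
ideal-gas expectation 4πr²dr·(N_aN_b − |overlap|)/V per frame, with
self-pairs excluded; r_max may not exceed half the shortest box edge.  Peak
picking smooths g(r) with a 3-bin moving average and reports local maxima
above g = 1.

**Coordination number.**  The deprotonation coordinate of an oxygen is the
smooth hydrogen count n = Σ_H (1 − (r/r₀)^p)/(1 − (r/r₀)^q) with
r₀ = 1.32 Å, p = 6, q = 12 (`obs.r0/p/q`), the standard rational switch for
O–H protonation counting; the removable singularity at r = r₀ evaluates to
p/q.

**Free energies.**  All free-energy estimates are unbiased negative-log
histograms, F = −kT ln p̂, min-subtracted, with unsampled bins undefined
(NaN).  Temperature defaults to 330 K (kT = 0.6558 kcal/mol), the elevated
production temperature used to mimic nuclear quantum effects.  The 1D
dissociation profile uses 100 bins over n ∈ [0, 2.5]; the dissociation free
energy ΔF_d is read off as the height of the first local maximum (first
derivative sign change on the 5-bin-smoothed profile) walking from the
global minimum (protonated basin, n ≈ 1) toward n = 0.  A monotone profile
raises an error rather than guessing.  An alternative fixed-coordinate
read-off (F at n_d, default 0.1) is available by flag.  The 2D conformer
surface histograms (α, β) on a periodic 72×72 grid (5° bins), resolving the
basins at (0,0), (0,±π)/(±π,0) and (±π,±π) at desk-scale sample counts.

## Wannier-center analysis

Precomputed maximally-localized Wannier-function centers (read from an
XYZ stream with species tag `X`, frame stride recorded against the
trajectory) attach to their nearest oxygen within 0.8 Å.  A center is a
*bonding* pair when it lies alongside a covalent bond — positive projection
onto the O→neighbor vector (H within 1.2 Å or C within 1.6 Å) not exceeding
the bond length, with perpendicular distance ≤ 0.45 Å — and a *lone* pair
otherwise, however close to the nucleus.  R(O–MLWF) distances are
histogrammed per oxygen role and conformer: for CT frames the trans
hydroxyl (O₂) is separated from the cis one (O₁); CC hydroxyls are pooled
(they are symmetry-equivalent); the carbonyl is tracked separately; the two
lone pairs per oxygen are pooled.  Bicarbonate/carbonate frames carry no
role assignment and are skipped with a count.

## Synthetic data: what it emulates and what it does not

The generators produce ground-truth-labeled inputs at two levels.

*Stochastic.*  A continuous-time Markov model over
{CC, CT, TT, HCO₃⁻, CO₃²⁻} sampled on a frame grid (embedded chain
P = I + Q·dt, simulated by geometric sojourns) emulates the conformer/state
time series.  The shipped calibration fixture fixes the stationary vector
at 81.3 / 12.4 / 0.3 mol % for CC/CT/TT with 0.005 % carbonate (trace
second dissociation) and the balance in bicarbonate; exchange flows obey
detailed balance and are chosen to give correlation times of a few ps so a
10⁶-step census resolves the populations.  The carbonate exchange flow is
set so the trace state is visited often (residence ≈ 0.25 ps) and its tiny
population estimate concentrates.  Episode scripts draw source conformer,
hop count, endpoint and Poisson rattle insertions i.i.d. from configured
distributions (calibrated fixture: CT source weight 58.1 %, homing 82.95 %
CT / 57.76 % CC, a hop-count distribution dominated by 2-hop events, 0.3
rattles per episode).  Coordination samples are inverse-CDF draws from
exp(−F_ref/kT) on a fine grid; the reference profiles use a flat-topped
(super-Gaussian) barrier at n ≈ 0.45 plus a small linear tilt and a
harmonic wall, amplitude-rescaled so the shipped read-off rule applied to
the exact profile returns the calibrated barrier (7.43 kcal/mol for CC,
4.31 for CT) exactly.  The flat barrier top makes the 5-bin smoothing of
the sampled histogram unbiased at the read-off point; the sample size
(2×10⁷) is chosen so the barrier-top bins of the CC profile (11.3 kT above
the basin) hold ~20 counts and the negative-log histogram is defined where
the read-off happens.

*Atomistic.*  The renderer realizes scripts or label sequences as
coordinates: an idealized planar acid (C–OH 1.34 Å, C=O 1.21 Å, O–H
0.97 Å — standard small-molecule values, well inside the classifier
cutoffs) with the requested dihedrals, water H-bond partners placed 2.8 Å
beyond each hydroxyl hydrogen, and remaining waters as jittered lattice
fill.  Scripted hops relocate the mobile proton between host oxygens across
one frame; each host is held ≥ 2 frames (0.2 ps at dt = 0.1 ps) so real
hops survive the default filter, while rattle insertions last one frame and
are removed by it.  Conformer changes are instant template switches —
classification is threshold-based, so intermediate interpolated frames
would add nothing the analysis consumes.  Thermal jitter is a rigid
per-molecule Gaussian displacement (σ = 0.05 Å): intermolecular geometry
fluctuates while internal coordinates, and hence scripted labels, stay
exact.

Passing the recovery suites therefore shows that the geometric/graph
pipeline inverts the generator exactly under realistic noise placement and
spacing; it does **not** validate force-field realism, water–water
dynamics, diffusion, or any electronic-structure quantity — the renderer's
waters are scaffolding, not liquid water.

## Numerical choices and degenerate inputs

- Units repo-wide: Å, ps, kcal/mol, K; k_B = 0.0019872041 kcal/(mol·K).
- Only orthorhombic cells; triclinic inputs are rejected loudly.
  Coordinates are stored as read (never auto-wrapped); every distance goes
  through the minimum-image displacement, whose components land in
  (−L/2, L/2].
- Interval durations are compared against `tau_commit` with a 1 ns slack so
  a residence of exactly the threshold built from accumulated frame times
  never misclassifies.
- Empty Wannier streams warn; a stream whose frame count does not divide
  the trajectory's is an error; the stride is recorded.
- The rattling filter, hydrogen assignment, ring census, Wannier
  assignment and the ΔF read-off each have an independently coded
  brute-force oracle in the test suite; the dihedral is cross-checked
  against MDAnalysis.

## Problem sizes used by the shipped recovery runs

Census: 10⁶ steps (3×10⁶ for the rare TT/CO₃²⁻ states).  Episodes: 10⁴
scripted episodes rendered with 12 waters in the 12.44 Å box (~10⁵ frames).
Free energies: 2×10⁷ coordination samples per conformer.  Transitions:
5×10³ motifs.  RDF: 2×10³ frames of 8 shell oxygens (Gaussian shell,
mean 2.83 Å, σ 0.1 Å) around the carbonyl oxygen.  These sizes resolve
every calibrated statistic within a few tenths of a percent (absolute) at
interactive runtimes.

## Known limitations

- Single-solute systems only; multi-acid boxes are out of scope.
- The H-bond criterion and ring definition are declared defaults, not
  fitted to any reference liquid structure.
- Escaped episodes at trajectory end are excluded from endpoint fractions,
  which slightly biases homing fractions on very short trajectories.
- Concerted-hop identity through bifurcating relays beyond the
  shared-intermediate rule is not resolved.
- No transport coefficients, metadynamics reweighting, or error bars beyond
  block averaging.
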