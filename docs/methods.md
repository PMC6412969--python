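# Methods

## Snapshot pools

Every analysis consumes a `TrajectoryPool`: a fixed atom table plus frames
drawn from the tail of replica simulations of one receptor–ligand complex.
Pool construction keeps the final `tail_ns` (default 10 ns) of each replica
on the half-open window `[t_end − tail_ns, t_end)` with `t_end` one frame
interval past the last stamp, subsampling uniformly by index when the source
frame rate exceeds `per_ns` (default 100 frames/ns). With the default three
replicas this yields 3000 snapshots per derivative. Construction is
deterministic; identical inputs select identical frames.

Residue identities are bound through a `ResidueRoleMap` rather than
hard-coded numbers, because μOR numbering differs between murine, rat and
human constructs. The defaults use the murine-construct numbers (D147,
Y148, W133, M151, W293, H297, W318, H319, Y326, Y336, D114, C217, I144,
V143, I296, I322, L219, L232, T218, S55, V300, Q124) and helix backbone
ranges H1 72–92, H2 104–128, H3 139–169, H4 185–204, H5 227–260,
H6 275–304, H7 314–338. One source list names W336 where every analysis
elsewhere uses Y336; the role map defaults to Y336 and the discrepancy is
noted here rather than silently resolved.

## Descriptors

**RMSD/RMSF.** Per-frame RMSD is measured after least-squares superposition
of the selection onto the reference (the pool's first frame by default);
RMSF is the per-atom RMS deviation about the time-mean position after
superposing each frame onto the first. Superposition is a deliberate choice
— it makes helix fluctuation measures insensitive to whole-system drift in
a membrane — and can be disabled (`fit=False`) for raw deviations. Both
RMSD and RMSF are computed and reported, labelled, since both appear in
practice for related but distinct questions (drift vs flexibility).

**Dihedrals.** χ₁ is N–CA–CB–XG and χ₂ is CA–CB–CG–XD with the distal atom
per rotamer-library convention (Asp χ₂ uses the OD1 branch selected by atom
name; His uses ND1; Met SD; Ile CG1/CD1). Angles follow the right-hand
(IUPAC) sign convention on (−180°, 180°]. Averages over a pool use the
circular mean; dispersion uses the circular standard deviation
√(−2 ln R̄) with SEM = sd/√n (no angular dispersion convention was
prescribed; this is the standard directional-statistics choice). A
resultant length below 10⁻⁶ means the mean direction is undefined and is
reported as missing, never as an arbitrary angle. Note the circular and
arithmetic means agree only asymptotically on narrow arcs (the deviation is
second order in the arc width), so summary tables always carry the circular
value.

**Hydration.** A water molecule counts if *any* of its atoms is within the
cutoff (default 5.0 Å) of *any* atom of the residue — molecule-level
counting, so a water reaching in with one hydrogen counts exactly once.

**Group tests.** `kruskal_wallis` and `one_way_anova` wrap the standard
scipy tests at α = 0.05. Fully tied data (every observation identical)
carry no evidence against equal location and are reported as p = 1 rather
than an error.

## Contact typing

The source analyses name contact types (hydrogen bond, hydrophobic,
aromatic) without geometric criteria, so the criteria here are the module's
own, taken from common interaction-fingerprint practice and fully
configurable (`ContactCriteria`): donor–acceptor heavy-atom distance
≤ 3.5 Å with D–H···A ≥ 120° when hydrogens are present (heavy-atom distance
alone otherwise); apolar heavy-atom pairs (C/S not bonded to N/O, with
ligand bonding taken from the fragment scheme's declarations — chosen so
thioether chains count as apolar) ≤ 4.5 Å; ring-centroid distance ≤ 5.5 Å
with no plane-angle term (the simplest criterion consistent with an
"aromatic" label; an angle term is a possible extension); N⁺ to carboxylate
oxygen ≤ 4.0 Å for the ionic type. Boundary values count as contacts. A
contact is recorded once per (fragment, residue, type) per frame no matter
how many atom pairs satisfy it. Hydrogen-bond rows record which atoms
matched, so backbone vs side-chain acceptors can be filtered downstream
without the module taking a position on either convention.

Frequencies are per-replica fractions aggregated as mean ± SEM with
SEM = sd/√n_replicas (missing for a single replica). The binding-mode
features default to: GF1 — salt-bridge persistence ≥ 0.5; GF2 — N-chain
hydrophobic contact with at least one of {I296, I322, W293, Y326} at mean
frequency ≥ 0.5; GF3 — propanamide with {I144, L219}; GF4 — anilide
aromatic with {C217, I144, V143, W133}; GF5 — 4-axial with W318, reported
as not-applicable when the ligand has no 4-axial substituent. The
threshold and the number of required partners are parameters, not claims.

## Dynamic volume

The fragment size measure is a classical electron-count-weighted second
moment in atomic units: Σᵢ nᵢ|rᵢ − c|² + Σᵢ nᵢρᵢ², with nᵢ the neutral-atom
electron count, c the electron-count-weighted centroid (positions converted
to bohr) and ρᵢ a per-element spread constant, by default the covalent
radius in bohr. It is translation/rotation invariant, monotone under
uniform expansion and under adding atoms — the same size ordering a
quantum-mechanical spatial-extent calculation provides — while remaining
desk-scale. Genuine quantum values, when available, are ingested per
snapshot through the `external_table` backend; the classical backend
documents its own centroid choice and claims no numerical equivalence to
any particular QM program's reference point. Averaging the per-snapshot
value over the pool folds rotational flexibility into one number per
fragment ("dynamic" volume); the combined N-chain + anilide-aromatic value
is the single variable used against affinity.

## SAR regression

pIC50 = 9 − log₁₀(IC50 in nM). Censored records (">1000 nM") are excluded
from all fits by default; chiral mixtures carry a flag so regressions can
exclude them. The two-segment model fits two independent least-squares
lines split at a breakpoint chosen by exhaustive search over midpoints of
consecutive distinct x values with at least two points per side, minimising
total SSE, ties toward the smaller breakpoint — exhaustive search is exact
and trivially cheap at n ≤ ~30. A split that fails to produce a genuine
ascending/descending pair falls back to the single-line fit, flagged. The
quadratic alternative is OLS on (1, x, x²) with R reported as the Pearson
correlation of fitted vs observed values and the vertex at −b/2a. Every
fit and correlation reports its n after exclusions and listwise deletion.

## Rescoring

Third-party scoring functions are consumed as exported per-snapshot tables;
none is re-implemented. "Optimal" is the maximum or minimum of the
per-snapshot totals according to a per-function direction declared with the
data; a mean-based aggregation is provided as the secondary analysis.
Reweighting is OLS of pIC50 on named components with the internal
(training) Pearson R reported; rank-deficient component matrices are
rejected with the collinear columns named. Internal R necessarily dominates
the best single-component correlation (OLS dominance), which is why the
external validation — predicting unseen compounds into a reference pIC50
band — is the meaningful check. Exclusion lists (chiral compounds, declared
outliers) are explicit configuration, never hard-coded.

## Synthetic data

The generator emulates the *statistical* structure of pooled production
output, not the physics: helices are straight backbone traces with
isotropic Gaussian noise; role-residue side chains are rebuilt per frame from
sampled χ angles by internal-coordinate placement; contacts are realised by
placing dedicated fragment probe atoms inside or outside the type-specific
cutoff band with the target per-frame probability; the salt bridge and the
3-7 lock place atoms at prescribed distances; hydration shells draw
Poisson-distributed waters at 2.6–4.7 Å. Role anchors sit ≥ 18 Å apart so a
probe placed "outside" its own residue's cutoff cannot graze a neighbour.

Defaults are the study conditions: 3 replicas × last 10 ns × 100 frames/ns;
per-coordinate backbone noise σ = 0.537 Å, chosen so the backbone RMSF mean
is σ√3 ≈ 0.93 Å, the level reported for this family; W293 χ₂ mean −100°
(the reported means span −92° to −111.7°) with sd 15°; lock distance
5.6 ± 0.25 Å (reported range 5.14–6.13 Å); salt-bridge presence 0.99
(">99 % of frames" for well-anchored derivatives); hydration rates
D114 = 4.0 and Y336 = 2.5 waters — no printed values exist for these, so
they are plausible first-shell counts fixed once. Contact-target
probabilities follow the qualitative pattern of the reported fingerprints
(I296/I322 ≈ 0.9, Y326 ≈ 0.8, W293 ≈ 0.5, etc.) and satisfy GF1–GF5.

The SAR generator's defaults (x grid 0–1150 a.u. in 24 steps, slopes
+0.008/−0.006 pIC50 per a.u., breakpoint 600, noise sd 0.2 pIC50) were set
by a signal-to-noise argument fixed before any fitting: the per-step signal
|slope|·Δx is 0.3–0.4 pIC50, 1.5–2× the noise sd, the regime in which a
breakpoint is identifiable from two dozen points.

Two emergent, chemically sensible artefacts of the geometric realisation
are worth knowing: the aromatic probe ring's carbons also register a
hydrophobic contact with the target residue whenever the ring is "in"
(aromatic stacking at 4–5 Å genuinely implies apolar proximity), and the
salt-bridge nitrogen registers a hydrogen bond to D147 and occasionally to
the lock-placed Y326 hydroxyl. Controlled targets are unaffected — the
generator's ground truth records realised per-frame indicators and the
detector recovers them exactly.

**What passing tests do and do not show.** Synthetic pools share the
statistical structure of real trajectory output (circular dihedral laws,
Poisson hydration, Bernoulli contacts, Gaussian backbone noise) but none of
its physics: no correlations across frames, no coupling between
descriptors, no force field, no membrane. Recovery tests therefore
demonstrate that the estimators are unbiased and correctly implemented at
realistic sample sizes — not that real simulations would show any
particular value.

## Numerical choices and degenerate inputs

Distances use boundary-inclusive comparisons (≤). Angles live on
(−180°, 180°]; −180° maps to +180°. Superposition uses SVD-based
least-squares rotation with proper-rotation enforcement. The breakpoint
search breaks ties toward the smaller value to make fits order-invariant
and reproducible. Empty fragments yield not-applicable records (volumes,
GF5) rather than errors; empty selections, missing role atoms, censored
IC50s in fits, single-frame RMSF, and rank-deficient designs raise typed
validation errors naming the offending object. Seeded randomness flows
through `numpy.random.default_rng`; pipeline stages derive child seeds via
`SeedSequence.spawn`, and two runs with the same configuration are
byte-identical (verified by sha256 in the run manifest).

## Problem sizes

The test suite runs pools of 3 × 100 frames with shortened helix ranges
(~300–1000 atoms); the acceptance script uses full-size pools (3 × 1000
snapshots, full helix ranges) for the descriptor-recovery quantities, 100
seeds for breakpoint recovery and 1000 null simulations for the test-size
calibration. These sizes give sampling errors comfortably below the
tolerances being checked while keeping the whole analysis interactive.

## Known limitations

- The classical dynamic-volume backend preserves size *ordering*, not QM
  magnitudes; analyses that need literal spatial-extent values must supply
  an external table.
- Hydrogen-bond detection degrades gracefully to a heavy-atom distance
  criterion on structures without hydrogens; with partial hydrogenation the
  donor/acceptor asymmetry of that fallback is approximate.
- The aromatic criterion has no plane-angle term, so edge-on and stacked
  geometries are not distinguished.
- Censored affinity records are excluded rather than modelled; no survival
  / Tobit-style treatment is attempted.
- The contact detector considers role-map residues only; residues outside
  the role map are invisible to fingerprints by design.
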