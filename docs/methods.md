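# Methods

## Data model

The unit of analysis is a pose ensemble: one compound (atoms, bonds,
reference coordinates) plus 1–10 docked conformations sharing the atom
order, each with a docking score (lower = better, the convention of
Glide-style programs). Ensembles arrive as multi-record V2000 SDF files
grouped by a compound-id SD tag, with the score in a per-record tag
(default `r_i_docking_score`) and optional precomputed charges in
`atom.dprop.PartialCharge`. Hydrogens are kept if present: descriptors
use all atoms in the input, while alignment and the atom-variability
mean use heavy atoms only, because docking programs place hydrogens
variably. This choice changes descriptor values, so it is stated here
prominently; both conventions can be produced by preprocessing the
input.

## Activity labelling

A compound is *active* when its Ki is strictly below 100 nM, *inactive*
strictly above 1000 nM, otherwise *ambiguous* (excluded from group
statistics but retained in correlations). When only an IC50 is known
the effective Ki is IC50/2; an explicit Ki always wins. The boundaries
100 and 1000 nM are ambiguous by the strict inequalities.

## Rotatable bonds

No universal definition exists; the package counts acyclic single bonds
between two heavy atoms that are each bonded to at least one other
heavy atom. Ring membership comes from bridge detection on the bond
graph. An optional flag additionally excludes amide C–N bonds for
cross-checks against toolkits that apply that exception; it is off by
default.

## Descriptors (237 per conformer)

All families are functions of interatomic distances, per-atom weights,
areas and charges, hence invariant under rigid motion, reflection and
atom reindexing.

* **3D-MoRSE** `morse_{w}_{s}`: Σ_{i<j} w_i w_j sinc(s·r_ij) with
  scattering parameter s = s_index − 1 for s_index 1..32 (Å⁻¹) and
  sinc(0) = 1. This offset convention is pinned by the observable fact
  that the first descriptor reduces to Σ_{i<j} w_i w_j — the pair count
  when unweighted — and is therefore *exactly* conformation-independent;
  any other offset would leave no invariant descriptor. Weighting
  schemes: unweighted, mass, vdW volume, Sanderson electronegativity,
  polarizability (each normalised by the carbon value, so w(C) = 1) and
  signed, unnormalised partial charge.
* **Gravitational** `grav_*`: Σ m_i m_j / r_ij² over all pairs and over
  bonded pairs, plus square- and cube-root forms (amu²/Å² and roots).
  Coincident atoms (r < 1e-6 Å) are a hard error: the geometry is
  degenerate, not merely undefined.
* **Inertia** `inertia_*`: eigenvalues of the inertia tensor about the
  centre of mass, ascending (amu·Å²), plus pairwise ratios; a ratio is
  NaN-flagged when its denominator is below 1e-10.
* **Geometric** `geom_radius`, `geom_diameter`, `petitjean_3d`,
  `shape_index_3d`: from distance-matrix eccentricities e_i = max_j
  r_ij, R = min e, D = max e, Petitjean (D − R)/R. The shape index has
  no single accepted 3D definition, so the variant is configurable:
  (D − R)/R (default) or D/R.
* **CPSA** (Stanton–Jurs): partial surface-area sums over positively
  and negatively charged atoms (PPSA/PNSA 1–3), differences, fractions
  of the total area, surface-weighted forms, relative-charge terms
  (RPCG/RNCG/RPCS/RNCS), and the |q| ≥ 0.2 polar-surface split
  (TASA/TPSA/RASA/RPSA). Empty-class *sums* are 0 (empty sums);
  *ratios* over an empty class are NaN-flagged. Undefined values are
  never silently zeroed — they are excluded per descriptor downstream,
  because imputation would bias std statistics.

### Surface model

Shrake–Rupley solvent-accessible areas: each atom's Bondi vdW sphere is
inflated by the probe radius (default 1.4 Å water probe, configurable
including 0) and sampled with a deterministic Fibonacci-spiral point
set (default 960 points; no RNG, so areas are bit-stable). A point is
accessible iff outside every other inflated sphere; the atom area is
the exposed fraction times the inflated-sphere area.

Because the point set has a fixed orientation, sampled areas would vary
~0.1–1% under rotation of the input. The descriptor pipeline therefore
evaluates SASA in a canonical shape frame: covariance eigenvectors
(ascending eigenvalue) with each axis signed so the mass-weighted third
moment along it is positive (fifth moment as tie-break, with a
noise-floor threshold so near-zero moments fall through). Proper
rotations, reflections and translations all map to the same canonical
coordinates, making the CPSA family isometry-invariant to ~1e-12 like
the analytic families. Degenerate shapes — equal covariance
eigenvalues, or all odd moments vanishing — keep an arbitrary but
deterministic axis choice; in the vanishing-moment case the flip is a
genuine shape symmetry and either choice yields the same areas.

### Charge model

Gasteiger–Marsili PEOE with the classic (a, b, c) electronegativity
polynomials for H, C, N, O, F, P, S, Cl, Br, I by hybridisation class
(inferred from bond orders), damping (1/2)^n at iteration n, 8
iterations. Transfers are antisymmetric, so the total formal charge is
conserved exactly. Charges supplied in the input SDF take precedence;
the model only fills gaps (configurable to always recompute). Elements
outside the parameter table must arrive with precomputed charges.

## Alignment and atom variability

Kabsch superposition (SVD with determinant correction, proper rotations
only) of each selected pose onto the best-scoring pose, over heavy
atoms; fewer than three non-collinear atoms is an error. Per-atom
RMSF = sqrt( mean_p ||x_pa − μ_a||² ) about the mean aligned position
(3D positional deviation, not per-axis), population divisor by default
with a ddof switch; the compound value is the mean over heavy atoms.
Pairwise-to-reference alignment was chosen over iterative-to-mean: the
reference (best-scoring pose, ties by file order) makes the statistic
deterministic, and only relative comparisons are consumed downstream.

## Consistency pipeline

1. Descriptor table: one row per (compound, pose), stable column order.
2. Standardisation: per-descriptor z-scaling fitted over all rows;
   descriptors with std < 1e-12 or > 50% undefined entries are dropped
   and logged. Standardisation is on by default because the raw scales
   differ by orders of magnitude and an "average std over descriptors"
   is only meaningful on a common scale; a raw-scale mode remains for
   the per-descriptor summary, which reports both scales.
3. Top-k selection (k ∈ {3, 5, 10} by default) by ascending docking
   score, ties by file order; compounds left with fewer than two poses
   are recorded in a skip log, never silently dropped.
4. Per-compound descriptor std (mean over retained descriptors of the
   per-descriptor std across poses; population divisor, switchable) and
   atom std; rotatable-bond count; activity label.
5. Group summary per k (means per class, actives-higher indicators;
   empty groups reported missing, not zero), Pearson correlation of
   (rotatable bonds, descriptor std) per k (NaN-flagged under zero
   variance or n < 3), and the per-descriptor variability ranking.

Scaling any raw descriptor column by a positive constant leaves the
standardised consistency score unchanged — the property that justifies
step 2.

## Synthetic benchmark

The generator emulates the statistical structure of a docking campaign
without any docking program. Molecules are branched heavy-atom chains:
a backbone of n_rot + 3 atoms (an L-chain has L − 3 rotatable bonds)
plus terminal branches that leave the rotor count unchanged, ideal
1.5 Å bonds, tetrahedral angles, random C/N/O decoration so that all
weighting schemes and charges are non-trivial. Poses perturb every
rotatable torsion by N(0, sd²) with a class-specific sd, add 0.05 Å
isotropic jitter, and apply a random rigid motion; the docking score is
the RMS torsion perturbation plus N(0, 0.2²), so top-k keeps the least
perturbed poses. Ki values are sampled log-uniform inside (1, 100) nM
for actives and (10³, 10⁵) nM for inactives, uniform in (100, 1000) for
the 10% ambiguous compounds; every fifth record reports IC50 = 2·Ki
only, exercising the IC50 path. One RNG stream per compound keyed by
(seed, index) keeps datasets stable under n_compounds changes.

Defaults (n = 200 compounds, 1–10 rotatable bonds, 10 poses, torsion
noise 0.9 rad active / 0.6 rad inactive) were fixed once so that
compound mean RMSF lands near the 0.5–1.0 Å scale typical of redocking
ensembles; with molecules of 4–15 heavy atoms the achieved range is
≈ 0.3–0.6 Å across k = 3..10, the same order of magnitude. What the
generator does *not* emulate: receptor pockets, scoring-function
energetics, pose clustering/flips, protonation states, or drug-sized
molecules (30+ heavy atoms). A green benchmark test therefore
establishes that the pipeline recovers planted flexibility and class
effects — not that any particular receptor dataset would show them.

## Embedding

Per-compound vectors of per-descriptor stds (standardised scale,
remaining NaNs zeroed to keep one dimension) are projected to 2D by PCA
or classical (Torgerson) metric MDS — both deterministic; on centred
Euclidean data they agree up to rotation/reflection. A stochastic
neighbour embedding can be slotted in by callers who accept
non-reproducible layouts. The export writes x, y, compound id, label,
colour (red = active, black = inactive, grey otherwise), consistency
scores and optional SMILES, as CSV or JSON-lines.

## Numerical conventions and degenerate inputs

* Population (n) std everywhere by default; ddof switches exposed since
  class comparisons are divisor-invariant.
* Ties in docking scores broken by file order (stable argsort).
* All CSV output uses a fixed float format; identical inputs and
  configuration give byte-identical files, and a benchmark manifest
  replays to a byte-identical SDF.
* Coincident atoms: error in gravitational indexes; NaN-flag in
  geometric indexes (R < 1e-6); all-zero inertia ratios NaN.
* Collinear or < 3-atom alignment masks: error, propagated as a skip
  with reason at the pipeline level.

## Known limitations

* The descriptor inventory (237 values) follows the five classic 3D
  families but is not guaranteed to match any specific third-party
  implementation's inventory or conventions (e.g. which surface or
  charge model a given CPSA implementation uses is rarely documented).
* Gasteiger parameters cover organic chemistry (H, C, N, O, S, P,
  halogens); other elements require input charges.
* The canonical SASA frame is undefined for shapes with exactly
  degenerate covariance eigenvalues (spheres, symmetric tops); such
  inputs get a deterministic but arbitrary orientation, and sampled
  areas may differ up to ~1% between symmetry-equivalent inputs.
* Poses must share atom order; no graph matching across tautomers or
  protomers.
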