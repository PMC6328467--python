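# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generator does and does not emulate, and
the design decisions taken where the underlying protocols left the choice
open.

## Coordinate frame and units

Coordinates are in Å, frames 0-based, and the frame period in ns comes from
configuration (default 1 ns/frame) because trajectory formats do not carry
it reliably.  The membrane normal is the +z axis of the input frame:
structures are assumed pre-oriented, as membrane-positioning servers
produce them.  Transmembrane-segment boundaries are likewise configuration,
not derivation: the shipped `segments_5fn2.yaml` records a conventional
annotation for the 5FN2 chain layout (PSEN1 TMD1–9, PEN-2 helices, APH-1a
TMDs) and is overridable; no deposited annotation fixes these ranges, so
quantities that depend on them (tilt spreads in particular) are
reproducible only under a stated segment convention.

## Superposition and RMSD statistics

Superposition minimizes the weighted least-squares residual (Kabsch); the
implementation delegates the rotation solve to
`scipy.spatial.transform.Rotation.align_vectors` and the test suite checks
it against an independent quaternion-eigenvalue (Horn) oracle to 1e-6 Å.
`align_trajectory` fits each frame's fit-selection onto the reference and
applies the transform to **all** atoms, so waters and lipids are carried
into the protein frame — the prerequisite for box counting and lipid
B-factors.

Per-residue RMSD maps use Cα atoms by default (configurable); residues
missing the atom class are flagged NaN, never silently zero.  The
noise-subtracted heatmap is the entrywise `|cross − self|` of two maps
sharing residues and frame counts.  The mean structure is the arithmetic
per-atom mean of aligned frames.

B-factors follow the crystallographic convention
`B = (8π²/3)·⟨|r − ⟨r⟩|²⟩`, so isotropic jitter of per-coordinate σ gives
`B = 8π²σ²`.  Residue-level B is the residue's Cα value; chain-level B the
mean over member atoms.  The alignment reference is the trajectory mean for
protein residues and the first frame for lipids (both configurable),
mirroring the two uses of the protocol.  Note one systematic effect tested
explicitly: fitting on the same atoms whose fluctuations are measured
absorbs six rigid degrees of freedom, biasing B by a factor ≈ (1 − 6/3N);
with hundreds of fit atoms this is below 1%.

The radius of gyration is unweighted by default (Cα selections have equal
mass anyway); mass weighting is available.

## Collective motions

PCA eigendecomposes the 3M×3M covariance of the measure atoms' Cartesian
deviations from their mean after alignment on the fit selection, with the
unbiased (N−1) normalization and no mass weighting.  Eigenvalues are
clipped at zero against round-off; eigenvector sign is canonicalized
(largest-magnitude component positive) so outputs are deterministic.
Variance fractions are over all modes.  Mode extremes are
`mean ± a·√λ_k·v_k`, exportable as a two-model PDB; a mode with
λ ≤ 1e-10 Å² is treated as zero-variance and refused.

## Tilt protocols

The helix axis is the principal axis of the helix's Cα point cloud,
oriented N→C — robust to end fraying and standard practice; the alternative
COM protocol takes the unit vector from the intracellular to the
extracellular Cα centroid of a domain.  Every structure or frame is first
superposed on a common reference using the fit selection (PS1 TMDs
4, 5, 7, 8, 9 Cα in the canonical use), and θ is measured against the
mutual +z axis.  Whether that z is a global box axis or a per-structure
membrane normal is ambiguous in the source protocols; this package uses the
pre-oriented +z of the common reference frame.  The ensemble spread is the
sample (N−1) standard deviation; with a four-member ensemble the N vs N−1
choice moves the value by ~15%, so `ddof` is exposed and defaults to 1.
For ensembles of independently solved structures with different resolved
residues, `ensemble_tilt_from_structures` fits on the intersection of
(subunit, residue, atom) keys present in every member.

## State segmentation

The monitored distance series is smoothed with a centered running mean
(window 100 frames by default, clamped at the edges — centered so the
changepoint estimate carries no lag) and split at the exact least-squares
single changepoint: the index minimizing total within-segment squared
deviation, computed in O(n) from cumulative sums and verified against an
exhaustive-split oracle.  For distance-type series the higher-mean segment
is labeled *inactive* (far aspartates); this orientation rule is recorded
in the output.  A symmetric buffer (default 50 frames each side) around the
changepoint is excluded, and all per-state statistics are computed on the
raw, un-averaged series.  A zero-variance series yields a single state and
no transition.

Hydrogen-bond classification uses heavy-atom geometry: closest
donor–acceptor pair ≤ 3.5 Å, plus a D–H···A angle ≥ 120° when hydrogens
are present; a water bridge requires one water oxygen within 3.5 Å of at
least one carboxyl oxygen of *each* aspartate simultaneously.  The cutoffs
are the conventional values — the source protocols state none — and are
parameters.

## Hydration and lipids

Waters are represented by their oxygen for all counting.  Boxes are
axis-aligned in the fitted frame with half-open bounds `[lo, hi)` per axis
so counts partition space; when a box carries an anchor selection, the
trajectory's alignment is verified (maximum anchor deviation from the
reference below a threshold, default 5 Å) before counting.  The interior
box (30×28×36 Å ≈ 30 200 Å³) and binding-region box (27×18×16 Å ≈
7 800 Å³) ship as presets; their centers are a convention anchored to the
active-site midpoint, since none is published.  The density profile is the
per-z-bin mean density divided by the bulk-region mean density.

Lipid chains are scored by heavy-atom B-factors on the protein-aligned
trajectory after unwrapping each atom's periodic path by minimum-image
displacement accumulation — a chain hopping the boundary must not inflate
its B.  The table is ranked ascending; the `top_n` most immobilized chains
(17 in the canonical use; whether the original count was a threshold or a
fixed count is unclear, so `top_n` is exposed) are assigned to binding
sites by the set of protein segments they contact (heavy-atom distance
≤ 4.5 Å) in at least 50% of frames; the persistence threshold separates
resident from transient lipids and is configurable.

## The synthetic generator

No trajectories are deposited with the study this package re-implements,
so the generator is a first-class module that emulates the *statistical*
structure the analyses assume — it samples fluctuations, it does not
integrate physics.  There are no forces, thermostats or lipid chemistry;
consequently passing tests demonstrate that the analysis operators recover
known distributional structure at realistic magnitudes, not that they
would be robust to force-field artifacts, correlated solvent dynamics or
non-Gaussian protein motions in real trajectories.

The toy complex is a bundle of ideal α-helices (rise 1.5 Å/residue, 100°
twist, Cα plus a Cβ-like pseudo-atom per residue) placed on per-subunit
circles: nine PS1 helices numbered so the catalytic residues carry their
canonical ids (257 on TMD6, 385 on TMD7, with CG/OD1/OD2 pseudo-atoms),
three PEN-2 and seven APH-1a helices.  On top of the reference geometry the
generator plants, per frame:

* per-residue isotropic Gaussian jitter with prescribed σ (default 0.4 Å
  per coordinate, per-segment overrides) — target B = 8π²σ²;
* optional orthonormal random collective modes with prescribed variances,
  projected orthogonal to the rigid-body subspace (an alignment-based PCA
  can only observe the quotient of a mode by rigid motion) and optionally
  supported on the Cα subspace so the planted variance is fully visible to
  a Cα analysis;
* the two-state catalytic process: Cα–Cα distance N(9.1, 0.6²) before the
  transition frame (1750 of 3500 by default); after it a 26%/74% mixture
  of hydrogen-bonded N(7.5, 0.3²) and water-bridged N(8.6, 0.4²) frames —
  a mixture whose moments reproduce the quoted active-state 8.3 ± 0.6 Å;
  Cγ–Cγ analogously (8.0 ± 0.7 → mixture of 4.6/6.5, upper-clipped at
  9.4 Å to keep the carboxyl gap reachable by a single bridging water);
  whole-segment inward shifts of TMDs 6, 7 and 1 produce the per-residue
  RMSD signature and the radius-of-gyration contraction;
* tilt wobble: one helix rotated per frame about an in-plane axis by
  N(mean, σ²) degrees, default 15 ± 2°;
* solvent: fixed-count uniform bulk slabs above and below the membrane
  (desk-scale density 0.0045 Å⁻³), per-frame interior counts drawn from
  the planted state-dependent distributions (binding region 34.8 with
  σ 4.4 → 3.0; interior total ≈ 123), and explicit dual-proximity waters
  (per-state Poisson means 1.0 / 2.6) placed from the actual carboxyl
  positions — bridging water at the midpoint in bridged frames, otherwise
  on a 3.6–4.0 Å shell that is dual-proximal at the 4 Å cutoff but never
  bridging at 3.5 Å; uniform placements are rejected from the dual lens so
  the explicit waters are the only dual-proximal ones.  Unused water atoms
  are parked far outside every counting region to keep the atom count
  constant;
* lipids: rigid bead chains in a leaflet plane; 290 diffusive walkers with
  fixed 1 Å steps and periodic xy wrap, 10 trapped chains fluctuating with
  σ = 0.8 Å about sites placed outward of the angular midpoint between
  adjacent PS1 helix pairs (planar tether, so the expected chain B is
  (8π²/3)·2σ²).  The linear MSD growth of the walkers guarantees the
  trapped/diffusive separation at the default 3500 frames.

A single master seed derives the per-component streams; identical
(spec, seed) pairs are byte-identical.  Every planted quantity is written
to a `GroundTruth` manifest keyed to match the corresponding analysis
output.

## Problem sizes

The shipped validation runs use 3500-frame full systems (~3700 atoms) for
the state/hydration/lipid analyses, 10⁴ frames (protein only) for B-factor
field recovery, 5000 frames for the two-mode PCA split and 1000 frames for
tilt-spread recovery — sizes at which every recovery tolerance is several
sampling standard errors wide while the whole suite completes in about a
minute.

## Known limitations

* Periodic handling is orthorhombic only; alignment does not re-wrap, so
  analyses that mix rotation and periodicity must unwrap first (as the
  lipid stage does).
* The segmentation model is two-state with a single changepoint; multi-state
  or kinetic (MSM) models are out of scope.
* Real-ensemble quantities (Cryo-EM tilt spreads, active-site span) depend
  on the segment convention and on fetching the public structures; they are
  not derivable from the synthetic stand-in.
* Water bridges are classified by the oxygen positions only; hydrogen-atom
  geometry enters only the direct hydrogen-bond criterion, and only when
  hydrogens exist in the topology.
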