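# Methods

## Scope and pipeline

helixgeom quantifies the joint geometry of an antiparallel α-helix pair —
archetypally the G-ALPHA1/G-ALPHA2 helices flanking the MHC class I
peptide-binding groove — across the frames of a conformational trajectory.
Per frame and per polynomial degree m the pipeline runs: PCA reference frame
→ spline fit → discretisation at M positions → rulings → distance profile
d(uᵢ) and triangulated ruled-surface area A. Frames are processed
independently; no state is carried between them, so permuting the input
frames permutes the output series identically.

## Reference frames

The frame of a helix is the centroid of its Cα cloud plus the eigenvectors
of the coordinate covariance (sample covariance, ddof = 1; the divisor only
scales the reported eigenvalues, never the axes). Signs are fixed so that
PC1 points from the N- toward the C-terminal residue, PC2 toward the first
residue, and PC3 = PC1 × PC2 (right-handed, det +1). All downstream global
quantities are invariant to these conventions; they exist so that
coefficient-level results are deterministic and comparable across frames.
For a perfectly straight trace the two lateral eigenvalues vanish and
PC2/PC3 are an arbitrary orthonormal completion — harmless, because both
lateral fits are then identically zero. An ideal (unbent) helix has *tied*
lateral eigenvalues, so PC2/PC3 may rotate freely in the lateral plane
between frames; again only the coefficients, not the global curve, are
affected. Coincident points raise a degeneracy error.

## Spline model

In its frame each helix is the curve c(z) = (z, f₂(z), f₃(z)): z is the PC1
coordinate used directly as the curve parameter, and f₂, f₃ are
single-segment polynomials (no interior knots) of degree m, default degrees
{2, 3, 4}. The fit is two independent one-dimensional ordinary least-squares
problems — (z, y₂) and (z, y₃) — solved by an SVD-based factorisation with
column scaling; explicit normal equations are never formed in library code
(an explicit normal-equation solver exists only as an independent oracle in
the test suite). Preconditions: at least m + 2 points (residual degrees of
freedom) and at least m + 1 distinct z values (else a rank error). rss is
the summed squared residual of both components.

Treating z as a fixed abscissa (rather than orthogonal-distance regression)
is the direct reading of fitting "in the PC1–PC2 plane"; for helix traces,
whose spread along PC1 dominates, the difference is negligible.

## Discretisation

The curve is sampled at M positions, uniform in z by default (the direct
reading of the curve parameterisation); uniform-in-arc-length resampling is
available via `spacing="arclength"` for users who want equidistant points
along the curve. M defaults to 1500 and positions are labelled 1-based;
the canonical distance-report positions at M = 1500 are
(1, 369, 737, 1105, 1471) — the two flanks plus three central points —
taken as literal defaults and rescaled proportionally for other M.

## Rulings, distances, area

Corresponding points are paired by equal index under the shared parameter u.
Orientation is resolved by total ruling length: the second curve's order is
reversed iff reversal shortens Σd(uᵢ). For groove-like geometries the two
sums differ by orders of magnitude, so the criterion is unambiguous and
works without sequence-direction metadata.

Each quad (p1ᵢ, p2ᵢ, p2ᵢ₊₁, p1ᵢ₊₁) is split along the fixed diagonal
p1ᵢ → p2ᵢ₊₁; triangle areas are half cross-product magnitudes. A fixed
diagonal keeps the computation deterministic. Its cost depends on surface
twist: for untwisted surfaces (e.g. one curve a rigid translate of the
other) quads are planar, both diagonals agree to round-off, and A converges
to the M → ∞ limit at second order; when the rulings rotate along the groove
(bent antiparallel pairs whose curvature is mirrored) the diagonal choice
introduces a first-order bias of order 10⁻⁴ relative at M = 1500. Distances
d(uᵢ) are exact for the discretised curves either way. Scaling coordinates
by s scales d by s and A by s² exactly; rigid motions leave both invariant.

## AIC and degree comparison

The package's AIC convention for one helix model is

    AIC = n ln(rss/n) + 2p,  n = 2·n_points,  p = 2·(m + 1),

i.e. the Gaussian-likelihood AIC with both component fits pooled. rss = 0
returns −∞ with a warning. This exact variant is a package convention —
reasonable alternatives (AICc, per-component AIC) order nested helix fits
the same way in practice. Time-averaged areas are compared across degrees as
percent change relative to a reference degree (default: the lowest degree).

Summary statistics use true extremes for whiskers and linear interpolation
between order statistics for quartiles (the common default convention);
area SD is the sample standard deviation (ddof = 1, zero for one frame).

## Synthetic generator

The generator emulates: ideal α-helix backbone geometry (1.5 Å rise per
residue, 3.6 residues per turn, 2.3 Å Cα radius — textbook values, used as
defaults), smooth axis bend expressed as two lateral-displacement
polynomials (so a degree-m fit has an exact ground truth), antiparallel
pairing by a proper 180° rotation (chirality preserved), sinusoidal
breathing of the pair separation with per-frame ground truth returned, and
isotropic Gaussian noise (helix-internal noise drawn once per helix from
its own seed; per-frame jitter from the trajectory seed). Identical specs
and seeds reproduce coordinates bitwise.

It does **not** emulate: full-atom backbones or side chains, physical force
fields or solvent, per-frame secondary-structure fraying (helix ranges are
fixed input), correlated thermal motion, or helix unwinding. Passing
recovery tests therefore demonstrates the correctness of the geometric
machinery under known ground truth, not the biological fidelity of any
particular MD system.

Bend coefficients in tests are kept gentle (a few Å of lateral sweep over a
~52 Å helix), matching real groove helices; strong mirrored curvature in an
antiparallel pair makes rulings cross and the ruled surface fold, which is
geometrically valid but not groove-like.

## I/O

Trajectories are multi-model PDB (one MODEL per frame); helices are selected
by chain and an inclusive author-numbered residue range from a small YAML
config. Ranges are constant across frames: per-frame reclassification of
helix boundaries would change the spline support length between frames and
conflate boundary motion with shape change. Only Cα atoms are read; altloc
other than blank/'A' is ignored; insertion codes raise an error rather than
being silently ordered. The writer emits CA-only fixed-width records
(occupancy 1.00, B-factor 0.00), and write→read round-trips coordinates to
the PDB format's 0.001 Å precision. In-memory units are Å/Ų throughout; a
single switch rescales written outputs to nm/nm² for comparison with
GROMACS-convention plots.

## Problem sizes and numerical choices

Default analyses use M = 1500 rulings; test and acceptance runs use short
synthetic trajectories (up to 64 frames, 21–36 residues per helix), a
100 000-ruling refinement as the convergence oracle, 100-instance
coefficient-recovery batches, and 20 random rigid motions — sizes chosen so
the whole suite completes in seconds while exercising every code path.
Tolerances: analytic oracles at 1e-9 relative; coefficient recovery at 1e-8
against the normal-equation oracle; invariance properties at 1e-6 relative;
breathing amplitude/period recovery within 5 % at 0.1 Å noise (the FFT
estimator is exact for integer cycle counts, so the tolerance budgets noise
only).

## Known limitations

- Equal-index pairing assumes the two splines cover opposite sides of the
  groove at comparable parameter speed; strongly unequal helix lengths skew
  the rulings (real groove helices are comparable).
- The minimum-length orientation rule could in principle mis-resolve
  near-symmetric degenerate geometries (e.g. two identical closed shapes);
  not reachable for helix pairs.
- Fixed-diagonal triangulation biases A at first order in 1/M on twisted
  surfaces (~10⁻⁴ relative at M = 1500); switch diagonals or raise M to
  bound it.
- XTC/DCD trajectories are not read natively; convert to multi-model PDB
  first.
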