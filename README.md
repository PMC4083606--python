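# helixgeom

Geometric analysis of antiparallel α-helix pairs over conformational
trajectories, aimed at the two helices (G-ALPHA1 and G-ALPHA2) that flank the
peptide-binding groove of MHC class I molecules. Instead of tracking thousands
of atoms, each helix is reduced to a smooth space curve, and the pair to two
global quantities — the interhelical distance profile and the area of the
surface spanned between the helices — which measure the width and shape of the
binding cleft frame by frame along a molecular-dynamics trajectory.

## Model

For each helix in each frame:

1. **Reference frame.** The Cα coordinates are subjected to a principal
   component analysis. The centroid and the orthonormal axes PC1, PC2, PC3
   (descending variance) form the helix's local coordinate system; PC1
   approximates the helix axis.
2. **Spline fit.** In that frame the helix is modelled as the parametric curve

   `c(z) = (z, f₂(z), f₃(z))`,

   where `z` is the PC1 coordinate and `f₂`, `f₃` are single-segment
   polynomials of degree m ∈ {2, 3, 4} (K = 0 interior knots), fitted by
   ordinary least squares in the PC1–PC2 and PC1–PC3 planes.
3. **Discretisation and rulings.** Both splines are sampled at M = 1500
   positions under a common parameter u ∈ [0, 1]; "rulings" join equal-u
   points (the second curve's order is reversed when that shortens the total
   ruling length, which resolves the antiparallel pairing). The interhelical
   distance profile is

   `d(uᵢ) = ‖c₂(uᵢ) − c₁(uᵢ)‖, 1 ≤ i ≤ M`,

   reported at the five canonical positions 1, 369, 737, 1105, 1471
   (flanks + centre), and the ruled surface is triangulated quad by quad
   (fixed diagonal) to give the total area A.
4. **Summaries.** Per-position boxplot five-number summaries of d over time,
   the time-averaged area Ā with its SD, percent change of Ā between
   polynomial degrees, and an AIC per fitted model
   (`AIC = n·ln(rss/n) + 2p`, n = 2·n_points, p = 2(m+1)) for degree
   selection.

A synthetic-helix generator (ideal backbone geometry: 1.5 Å rise/residue,
3.6 residues/turn, 2.3 Å radius; configurable axis bend, separation,
sinusoidal "breathing", noise) provides trajectories with exact ground truth,
so every stage is testable without simulation data.

## Worked example

Simulate a breathing groove-like pair and analyse it:

```sh
helixgeom simulate --n-residues 36 --separation 14 \
    --breathing-amplitude 1.5 --breathing-period 8 --frame-noise-sigma 0.2 \
    --n-frames 32 --bend2 0,-0.08,0.002 --bend3 0,0.02 --seed 11 \
    --out groove.pdb --truth truth.csv

helixgeom analyze --pdb groove.pdb --config helices.yaml \
    --degrees 2,3,4 --npoints 1500 --out-dir results --dt-ns 0.05
```

with `helices.yaml` mapping labels to chains and residue ranges (the ranges
below fit the synthetic trajectory; for a real structure supply the helix
ranges of your PDB's author numbering):

```yaml
helices:
  G-ALPHA1: {chain: A, first_residue: 1, last_residue: 36}
  G-ALPHA2: {chain: B, first_residue: 1, last_residue: 36}
```

Printed output:

```
m=2: time-averaged area = 736.111 A^2 over 32 frames
m=3: time-averaged area = 736.699 A^2 over 32 frames
m=4: time-averaged area = 736.815 A^2 over 32 frames
area change m=2 vs m=2: +0.00%
area change m=3 vs m=2: +0.08%
area change m=4 vs m=2: +0.10%
```

Ā ≈ 736 Ų is consistent with a ≈14 Å-wide groove spanned over ≈52 Å of
helix; the higher-degree fits bend slightly more with the data, enlarging the
time-averaged area by a fraction of a percent on this gently curved synthetic
pair. `results/` then holds, per degree, `timeseries_m{m}.csv`:

```
frame,time_ns,area,d_pos1,d_pos369,d_pos737,d_pos1105,d_pos1471,rss
0,0,734.639,14.7363,14.4869,14.1311,13.6685,13.1026,370.9
1,0.05,788.632,16.0179,15.4738,15.0284,14.6822,14.4366,383.135
...
```

(area in Ų, distances at the five positions in Å, total fit rss in Ų), a
full-precision JSON twin, `summary_m{m}.json` with the per-position
five-number summaries — e.g. the central position 737 here spans
12.45–15.61 Å with median 14.14 Å, tracking the imposed 14 ± 1.5 Å
breathing — and `degree_comparison.json`. The same machinery is available
as a library (`helixgeom.analyze_trajectory`, `run_analysis`, ...).

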