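# Methods

## The measurement problem

A laminin trimer lies on a support and is raster-scanned by an AFM tip at
~3 frames/s, producing height maps (topographs) in nm. The long arm — a
three-chain coiled-coil of ~2 nm diameter ending in the LG globule
cluster — appears as an elongated rod with a bulky terminal blob. In the
flexible isoform the rod kinks about a hinge; the quantity of interest is
the hinge's position in the protein sequence. The chain of inference is:

1. trace the rod backbone in every frame and find the kink (position +
   inter-arm angle);
2. measure the kink's arc distance from the apparent LG edge;
3. correct for the stretch of rod that is invisible because the LG cluster
   overlies the coiled-coil C-terminus (plus tip broadening);
4. convert nm to residues with the coiled-coil rise per residue;
5. subtract from the per-chain C-terminal residue numbers.

Every step sits in its own module (`trace_analysis`, `hinge_map`) behind
the image-formation model in `afm_simulate` and the data types in
`core_io`.

## Image formation and tip geometry

A rigid tip touching a rigid surface produces the gray-scale dilation

    out(x, y) = max over (u, v) of [ true(u, v) − f(dist((x,y),(u,v))) ],

with `f` the tip apex profile: a sphere of radius `R_s` capped tangentially
by a cone of half-angle `α` (value- and slope-continuous at
`d* = R_s cos α`). The implementation truncates the dilation window where
`f` exceeds the image height range — exact, because a farther pixel is
penalised by more than the total relief — and is tested for bit-exact
agreement with an `O(N²M²)` brute-force oracle on images up to 32×32.
Pseudo-AFM rendering of a PDB structure rasterises the hard-sphere top
surface (per-pixel max of `z_i + √(r_i² − d_i²)` over atom vdW spheres) at
fine resolution (≤ 0.5 nm, an integer number of sub-steps per scan pixel),
dilates, then block-max resamples to the scan grid. Defaults follow the
published simulation parameters: scan step 1 nm, `R_s` = 1 nm, `α` = 5°;
the obscuration geometry uses the 2-nm imaging tip instead.

## Synthetic movie generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions and are not tuned per experiment.

* **Backbone.** Two discrete worm-like-chain arms (tangent increments
  `N(0, √(step/ℓ_p))`, step = pixel/2, persistence length ℓ_p = 300 nm so
  arms read "primarily straight") joined so the angle between the arms'
  end-to-end directions equals the per-frame hinge angle exactly.
  Conformations whose segments properly cross are resampled; mere
  side-by-side proximity is allowed, because a back-folded molecule
  (angle → 0°) legitimately lays its arms parallel.
* **Geometry.** C-terminal arm 33 nm from the coiled-coil terminus to the
  hinge, N-terminal arm 43 nm. The LG globule is a spherical cap
  (footprint radius 4.5 nm, height 4.0 nm — the scale of an LG1-3 cluster
  lying flat) whose centre sits on the backbone 4.5 nm from the terminus,
  so ~9 nm of rod run under the cluster. The *visible* quantities are then
  ~24 nm kink-to-LG and ~67 nm contour from the apparent LG edge, matching
  the reported morphometry; rod height 2.0 nm, base width 2.2 nm
  (semi-elliptical cross-section).
* **Dynamics.** Hinge angle: exact stationary OU discretisation, mean 63°,
  sd 25°, relaxation 2 s, Δt = 1/3 s, clamped to [0°, 180°] (the angle is
  a fold magnitude; its sign is unobservable in a topograph). Arm tangent
  noise is AR(1) across frames (ρ = 0.8) for shape coherence.
* **Imaging.** True surface = max(rod, LG cap), dilated with the 2-nm tip,
  plus i.i.d. Gaussian pixel noise (σ = 0.15 nm, a level at which
  molecules are cleanly segmentable). Pixel 1 nm.
* **Stiff control.** The S-shaped mode chains straight 13.2-nm tails and
  two opposite 120° arcs of radii 9.2 and 9.7 nm (contour ~66 nm) with a
  few degrees of per-frame arc jitter — a stable, hinge-free molecule for
  kink-detection specificity.

What the generator does **not** emulate: scanner artifacts (line noise,
drift, parachuting), molecule crowding and entanglement, 3-D adsorption
changes, tip wear or asymmetric tips, and the short arms of the real
molecule. Passing the recovery tests therefore demonstrates estimator
correctness under the stated imaging model, not robustness to every
instrumental pathology of real data.

## Estimators

* **Segmentation:** threshold at background median + 4·σ (σ from the
  median absolute deviation), 8-connected components, border-touching and
  small components dropped.
* **Backbone:** skeletonize → prune spurs < 3 px → longest (weighted)
  path; cyclic skeletons (self-overlap) are rejected. Components are
  flagged globular when the inertia axis ratio is < 2 *and* the skeleton
  slenderness (skeleton length / mean mask width) is < 4 — the second
  clause keeps strongly bent filaments, whose axis ratio alone drops
  below 2. Points are refined to sub-pixel by the height-weighted centroid
  across the local normal (±3 px, shift clamped to 1.5 px), smoothed with
  a 3-point moving average, and each end is extended along the outward
  tangent to the 0.8·(rod level) height point, compensating the skeleton's
  end retraction (residual contour bias ≈ +1 nm on straight rods).
* **Kink:** exhaustive breakpoint search minimising the summed squared
  orthogonal residuals of total-least-squares lines on the two
  sub-polylines (3 points excluded at each end); angle between the outward
  arm directions; improvement = single-line SSE / two-segment SSE. A kink
  is *called* at improvement ≥ 2 and angle ≤ 150° (defaults, exposed per
  call). The estimator equals a brute-force oracle on traces ≤ 30 points.
* **Apparent LG edge:** walking from the blob apex, the first backbone
  point whose smoothed height falls below half prominence
  (rod level + 0.5·(apex − rod level)). On synthetic ground truth this
  edge sits within ~1 nm of where the tip-dilated LG profile crosses the
  rod height, the definition used by the obscuration model.
* **Vertex-corrected contour:** with a finite tip the arms merge near a
  strong kink and the skeleton cuts the corner; when a kink is called, the
  merge-affected stretch (set by apparent width and angle) is replaced by
  straight legs meeting at the intersection of the fitted arm lines — the
  vertex a human tracer would draw.
* **Resolved-frame classification and the angle population.** A molecule
  folded beyond ~40° lays its arms side by side; the tip merges them and
  the trace covers only part of the molecule. Such frames are identified
  without ground truth (missing trace, apparent width > 1.2× the
  population median, or pseudo-straight yet much shorter than the median
  contour) and counted as *left-censored at 40°* in a censored-normal MLE
  for the angle population. The 40° resolvability limit is calibrated on
  synthetic ground truth (the flagging probability crosses 50% near
  37-40°). The censoring correction removes the ≈ +10° selection bias a
  naive mean over resolved frames would carry; both numbers are reported.
  Population surveys use independent single-frame molecules because the
  OU autocorrelation (integrated time ≈ 12 frames at the defaults) makes
  consecutive frames nearly redundant for population statistics.
* **Circle fits:** Taubin algebraic total-least-squares; exact on
  noiseless circles, circumcircle on 3 points; collinear input raises
  ("radius unbounded"). For S-shapes, the two fitted stretches grow from
  each half's curvature peak while curvature stays ≥ 0.7× the peak.
* **Tracking:** nearest-centroid linking within 15 nm, gaps ≤ 2 frames
  bridged, ambiguous links split the track, tracks < 5 frames dropped.

## Obscuration model

The LG profile is a 1-D axial height profile whose origin `s = 0` is the
true coiled-coil C-terminus, `s` increasing along the rod. The obscured
length is the distance from the terminus to the last point where the
tip-dilated profile is ≥ the rod height — the stretch of rod not visible
as a distinct feature. It decomposes into the physically covered extent
(the cluster overlies the terminus; crystal structures of laminin
fragments show the coiled-coil running to the basal side of LG1-3) and
the convolution broadening of the apparent edge; both parts are reported.
With no overhang the tip → 0 limit correctly gives 0. Profiles come either
from a structure (upper envelope of the LG atoms' vdW spheres projected on
the coiled-coil principal axis, the molecule assumed laid flat) or from a
spherical-cap parameterisation (defaults: footprint radius 4.5 nm, height
4.0 nm, terminus at the distal footprint edge). With the 2-nm tip these
give ~10.1 and 9.0 nm respectively — the model-dependent ~9 nm scale.

## Structure calibrations

Offline, the calibration inputs are synthetic canonical-geometry
standards (`synthetic_structures`): a poly-Ala α-helix (rise 1.5 Å/res,
radius 2.3 Å, 100°/res), an ideal trimeric coiled-coil (Crick-style, axial
translation 1.49 Å/res, supercoil radius 6.8 Å, left-handed pitch 140 Å),
and an E8-like assembly adding three 3.5-nm pseudo-sphere LG domains over
the C-terminal 9 nm of the rod. `rise_per_residue` projects the selected
Cα atoms on their first principal component and divides the peak-to-peak
extent by (residues − 1); on the standards it returns 0.149-0.150 nm/AA,
and it is rigid-motion invariant to 1e-6. All calibration functions accept
arbitrary PDB files; the standards stand in only because no crystal
structure ships with the package.

## Superposition

Kabsch: SVD of the cross-covariance with the determinant correction
(proper rotations only), single pass, all chains jointly under an explicit
chain map with per-chain residue-number offsets. Cross-checked against an
SVD-free optimisation oracle (random rotation search + Nelder-Mead on the
rotation vector) to 1e-3 Å and against 1000 random rotations for
optimality. Predicted-model validation offline uses a perturbed copy of
the reference with a planted deviation; the planted RMSD (`√3·σ` per
coordinate) is recovered within 10%.

## Numerical choices and problem sizes

Degenerate inputs raise rather than guess: missing pixel-size metadata,
NaN pixels, HETATM-only PDB files, collinear circle/superposition inputs,
offsets beyond a chain's length. Dilation window truncation is exact (see
above). Population checks run on a few hundred independent synthetic
molecules (400 in the acceptance script, 300 in the test suite) — enough
to hold the angle-population estimate within ~±1.5° and the residue-offset
recovery within ±10 residues; unit-level oracles run on small grids
(≤ 32×32 images, ≤ 30-point traces) where brute force is exact.

## Known limitations

* All estimators are automated surrogates for measurements originally done
  by hand; the acceptance surface is ground-truth recovery on synthetic
  data, not digit-for-digit reproduction of published histograms (the raw
  movies are not deposited).
* The kink-angle estimate carries a small orientation dependence from
  pixel-grid anisotropy (≤ ~2° on noise-free frames) and the LG-edge
  localisation a residual ~1 nm bias, folded into the stated tolerances.
* Molecules back-folded beyond ~40° are not measurable individually; the
  censored fit recovers the population mean but not their per-frame
  angles.
* The obscured length is model-dependent at the ±1-1.5 nm level (LG
  cluster dimensions and resting orientation); per-chain C-terminal
  residue numbers are user inputs and the α3 default is inferred, flagged
  as such in reports.
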