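# lamhinge

Quantitative localisation of a dynamic hinge in a laminin coiled-coil from
high-speed AFM (HS-AFM) movies.

Laminins are cross-shaped extracellular-matrix trimers whose three chains
(α, β, γ) wind into a single long coiled-coil "long arm" ending in the
globular LG domain cluster. HS-AFM shows that in laminin-332 this
coiled-coil kinks back and forth about a localised hinge, while the
laminin-111 coiled-coil holds a stable S-shape. This package implements the
full analysis chain that turns such movies into a sequence position for the
hinge, for researchers doing single-molecule AFM image analysis:

* **Backbone morphometry** — segmentation, sub-pixel backbone tracing,
  contour length `L_c`, end-to-end distance `R`, bend-circle radii (Taubin
  fit), and a two-segment breakpoint search that reports the kink position
  and the inter-arm angle θ (180° = straight, 0° = back-folded).
* **Tip-convolution geometry** — contact-mode image formation as gray-scale
  dilation of the surface with a sphere-capped-cone tip apex
  `f(d) = R_s − √(R_s² − d²)` for `d ≤ R_s·cos α`, tangent cone beyond;
  pseudo-AFM rendering of atomistic PDB structures (hard-sphere surface,
  scan step 1 nm, tip sphere 1 nm, half-angle 5°).
* **nm → residue mapping** — the LG cluster overlies the coiled-coil
  C-terminus and obscures ~9 nm of rod from a 2-nm tip; the corrected hinge
  distance `D = d_measured + d_obscured` divided by the coiled-coil rise per
  residue (`≈ 0.15` nm/AA, calibrated from a coiled-coil structure by
  principal-axis projection of the Cα atoms) gives the residue offset from
  the C-terminus, `n = round(D / rise)`.
* **Cα superposition** — Kabsch least-squares rigid alignment with RMSD,
  for validating predicted coiled-coil models against crystal structures.
* **Synthetic HS-AFM movies with ground truth** — hinged worm-like-chain
  molecules whose hinge angle follows an Ornstein–Uhlenbeck process
  (AR(1) with autocorrelation `exp(−Δt/τ)`), a terminal LG globule,
  tip dilation and Gaussian pixel noise; plus a stiff S-shaped control.
  Every estimator is validated by parameter recovery against this
  generator, because the original movies are not publicly deposited.

## Worked example

The analysis is organised as numbered drivers under `analysis/`:

```
python analysis/01_simulate_movies.py      # synthetic movies + ground truth
python analysis/02_trace_morphometry.py    # per-frame traces, kinks, angles
python analysis/03_map_hinge.py            # nm -> residue conversion chain
python analysis/04_render_structures.py    # pseudo-AFM of the standards
python analysis/05_superpose_models.py     # Calpha RMSD validation
```

`03_map_hinge.py` runs the full chain on 300 independent synthetic
molecules and prints:

```
measured kink-to-LG: 22.52 ± 2.42 nm over 66 molecules
obscured coiled-coil: 10.06 nm (8.88 covered + 1.18 convolution)
rise: 0.1490 nm per residue
hinge offset: 219 residues from the C-terminus
per-chain hinge residues: {'alpha3': 2170, 'beta3': 946, 'gamma2': 964}
```

Reading: the kink sits ~22.5 nm from the apparent LG edge in the images;
adding the ~10 nm of coiled-coil hidden under (and broadened around) the
LG cluster and dividing by the 0.149 nm/AA rise places the hinge ~219
residues upstream of the coiled-coil C-terminus — near residue 2170 of the
α3 chain (C-termini per chain are config inputs in UniProt numbering,
flagged as inferred in the JSON report). Tables land under `results/`.

The desk arithmetic alone is two calls:

```python
from lamhinge.hinge_map import corrected_hinge_distance, residue_offset, RiseCalibration
cal = RiseCalibration(rise=0.15, source="printed", ranges=(), axial_extent_nm=33.0, residues_spanned=221)
corrected_hinge_distance(24.0, 9.0)        # 33.0 nm
residue_offset(33.0, cal)                  # 220 residues
```

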