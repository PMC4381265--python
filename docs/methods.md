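# Methods

## Dose model

All dosimetry operates on congruent regular voxel grids (identical shape,
spacing, origin; voxel-centre coordinates in mm). Planning-system and Monte
Carlo output on different grids must be resampled onto one common grid
first; `smnrisk.grids.resample_nearest` provides nearest-neighbour
resampling as plumbing. Because the voxel volume is uniform within a grid,
the mass-weighted organ mean

H_T = Σ_{v∈T} H_v ρ_v / Σ_{v∈T} ρ_v

is implemented with density weights only — the voxel volume cancels. Organ
masks are binary; partial-volume effects at organ boundaries are not
modelled, so organ means carry a discretisation error that shrinks with
voxel size.

Equivalent dose is the voxelwise product H_v = w̄_R · D_v with a single mean
radiation weighting factor per field type:

| field | w̄_R | rationale |
| --- | --- | --- |
| photon primary | 1.0 | low-LET reference radiation |
| proton primary | 1.1 | mean quality factor of therapeutic protons (so a 21.3 Gy plan delivers the 23.4 Gy-RBE prescription) |
| external neutrons | 9.2 | mid-range Monte Carlo value for a similarly sized paediatric patient |
| internal neutrons | 9.0 | average Monte Carlo value for a small-stature phantom |

Neutron weighting factors are configuration scalars, not energy-dependent
spectra: the upstream Monte Carlo literature supplies single representative
values, and the pipeline's contract is dose bookkeeping, not transport.

**Truncation correction.** CT images often stop mid-thigh. Volumes that
extend beyond the image (red bone marrow, skin, remainder, whole body) have
their means multiplied by the ratio of imaged body mass to total body mass
(0.726 for the bundled case), which assumes dose below the image is
negligible. The correction is expressed generically (ratio + organ set) so
other patients can supply their own.

**Density calibration.** CT numbers map to mass density through a
configurable piecewise-linear curve. The packaged default is a two-segment
air→water→bone curve ((−1000, 0.00121), (0, 1.0), (1300, 1.85) in
(HU, g/cm³)); clinical use should substitute the scanner's own calibration.
Out-of-domain CT numbers clamp to the nearest endpoint with a warning.

**DVH.** Differential, equal-width bins (default 1000) spanning the organ's
dose range; the bin-centre mean recovers the voxel mean to within half a bin
width, which is the testable accuracy bound. A uniform-dose organ receives
one degenerate-width bin.

## Stray-neutron normalization

Monte Carlo neutron doses arrive per source particle. A beam normalization
volume (BNV) — a contoured region of approximately uniform in-field dose,
treated here as an organ-style mask whose per-source-particle dose is the
same mass-weighted mean used for organs — anchors the scale: the number of
source particles is the one that makes the Monte Carlo BNV primary dose
match the planning-system BNV dose, and every per-source-particle organ
dose is multiplied by it. The operation is invariant under rescaling the
per-source-particle normalisation, which the property suite asserts.
External and internal neutron organ doses are summed after weighting and
normalization.

## Out-of-field photon dose

Planning systems are accurate in-field and unreliable out-of-field. Three
approaches are implemented and can be compared on the same case:

1. **TPS only** — voxel doses as exported.
2. **Volume-weighted averaging** — organs fully outside the 5 % isodose
   surface take the mean of their point (TLD-style) measurements. Partially
   in-field organs first pass a sensitivity test: scale the organ's
   sub-5 %-isodose voxels by 1 ± 0.6 and trigger only if either scaling
   moves the organ mean by more than 5 % in relative terms (both signs are
   tried because dose errors can go either way). Triggered organs blend the
   in-field planning-system mean with the measurement mean, weighted by the
   volume fraction inside the 5 % surface; untriggered organs keep the
   planning-system value.
3. **Model-based replacement** — voxels outside the 50 % isodose surface
   *and* more than 1 cm from its nearest vertex are replaced by the fitted
   two-Gaussian function of distance from the field edge (α₁ = 224.8
   cm·cGy/Gy, μ₁ = −2.16 cm, σ₁ = 1.57 cm, α₂ = 224.3 cm·cGy/Gy,
   μ₂ = −7.43 cm, σ₂ = 10.28 cm). The negative means place the peaks inside
   the field, so the model is strictly decreasing over the whole
   out-of-field range. Voxels in the 1 cm guard band keep planning-system
   values, both in the grid and in the subsequent organ averaging; in-field
   voxels are never touched (bit-identical before/after, asserted).

Distance to the field edge is the Euclidean distance to the *nearest
sampled vertex* of the isodose surface, not point-to-triangle; the vertex
sampling density therefore bounds the distance error, and the synthetic
generator samples vertices at or below the voxel spacing (marching-cubes
vertices). Whether a voxel is "inside" a surface is decided by its dose
exceeding the level threshold — a stand-in for the closed contoured
structure a planning system would export, and exactly consistent with how
the synthetic generator lays down dose. The default approach for risk
assessment is `model`, the most complete of the three.

## Risk projection

Lifetime attributable risk is linear-no-threshold: I_T = (I_T/H_T)·H_T and
M_T = (M_T/H_T)·H_T per site, with coefficients in %/Sv.
Twelve sites carry coefficients (stomach, colon, liver, lung, breast,
uterus, ovary, bladder, thyroid, leukemia, NMSC, other solid); leukemia is
driven by the red-bone-marrow dose, NMSC by skin, "other solid" by the
remainder volume (whole body minus all specific SMN-site organs).

Coefficient preparation mirrors how BEIR-VII-style endpoint tables are
turned into patient-specific coefficients: linear interpolation between
bracketing ages (e.g. a 13-year-old from the 10- and 15-year female
tables), removal of the DDREF of 1.5 for every site except leukemia
(therapeutic doses are far above the low-dose regime the DDREF corrects
for; the guard against double removal is part of the table's state), NMSC
coefficients carried as pre-derived ICRP-60-based constants, and thyroid
mortality as incidence × 0.1 lethality. The bundled 13-year-old female
table ships with DDREF already removed.

Under LNT, each site's proton:photon risk ratio equals its organ dose ratio,
identically for incidence and mortality — the suite asserts this structure.
Reported risks and ratios round to 2 decimals; the "ratio ≥ 1" flag is
evaluated on the rounded ratio, matching the reporting precision (skin doses
of 2.79 vs 2.80 Sv are equivalent at that precision, so NMSC flags as the
one site proton therapy does not improve). Component attribution divides the
coefficient-weighted dose of each component by the coefficient-weighted
total; with rounded bundled inputs the stray fraction is asserted as an
interval (0.20–0.27), not a point. Note the bundled external:internal
neutron organ-dose ratios span 1.42–4.57 — rounding of the two-decimal
inputs pushes the breast ratio (0.32/0.07) slightly above the mid-4 range
the unrounded data would give.

No uncertainty propagation is attempted on risk coefficients, and no
non-linear (cell-sterilisation) dose–response alternatives are offered.

## Synthetic phantom

The generator exists to make every pipeline stage testable without any
external data; it emulates structure, not anatomy.

* **Geometry**: an elliptic-cylinder torso, cylindrical neck and ellipsoidal
  head spanning 256 × 256 × 720 mm (default 64 × 64 × 160 voxels at
  4 × 4 × 4.5 mm); organs are ellipsoid/cylinder primitives carved in a
  fixed priority order so the specific organ masks are pairwise disjoint
  and subsets of the body; skin is a one-voxel body shell; red bone marrow
  is the spinal column plus cranial vault; remainder is derived by Boolean
  subtraction. The imaged mass is ≈ 20 kg and the truncation ratio defaults
  to 0.726.
* **Fields**: a posterior spinal slab (50 mm wide, z 180–565 mm) plus a
  cranial volume (z ≥ 555 mm). Photon fields traverse the whole
  anteroposterior extent (divergence and exit dose), so the thyroid is
  fully in-field; proton fields stop just anterior of the vertebral bodies.
  The pelvic organs sit ≈ 6 cm below the spinal field edge — outside the
  5 % isodose surface, reproducing the clinical classification of uterus,
  ovaries and bladder as fully out-of-field.
* **Photon dose**: prescription (23.4 Gy-RBE) in-field; outside, the
  two-Gaussian model evaluated at the nearest-vertex distance from the 50 %
  surface (marching-cubes vertices of the field region), times lognormal
  noise. At zero noise the out-of-field grid *is* the analytic model, which
  is what makes the 1 % end-to-end recovery check meaningful.
* **Proton dose**: physical dose 21.3 Gy in-target with a sharp Gaussian
  lateral/distal falloff (σ = 8 mm); neutron equivalent-dose fields decay
  exponentially with distance from the field (length scales 25 cm external,
  18 cm internal) with amplitudes chosen so organ means span roughly
  0.05–0.55 Sv, bracketing published proton-CSI neutron organ doses;
  external exceeds internal everywhere. Both neutron grids and a duplicate
  primary grid are emitted per source particle (2 × 10¹⁵ sp) to exercise
  BNV normalization end to end.
* **Noise**: multiplicative lognormal (default σ = 5 %, mean-one
  parameterisation), because dose uncertainties are relative; σ = 0 yields
  exactly deterministic grids. One global seed feeds named substreams
  (stream id = CRC32 of the stream name), so any component regenerates
  identically in isolation.
* **TLDs**: voxels sampled without replacement inside an organ; each
  measurement is the local equivalent dose times lognormal noise.

What passing tests on this phantom do **not** show: accuracy on real CT
textures, contour irregularity, heterogeneity corrections, inter-field
abutment effects, or any beam physics — the generator's doses are laid down
by the very models the pipeline fits, so end-to-end checks demonstrate
internal consistency and correct composition of the operations, not
dosimetric truth.

## Numerical and design choices

* Unit tags (`Gy`, `Sv`, `Gy/sp`, `Sv/sp`) are enforced at the
  equivalent-dose boundary; mixing units raises.
* Tests run the same phantom geometry on a coarsened 32 × 32 × 80 grid
  (identical physical extents) and the acceptance script on 48 × 48 × 120;
  the structure of every check is scale-independent.
* The reference-case organ-dose and coefficient tables are packaged
  constants so the risk engine has a deterministic, data-free regression
  surface; `smnrisk reproduce` prints that comparison.
* Degenerate inputs: empty masks, empty vertex lists, non-positive BNV
  doses, negative dose components, out-of-range interpolation ages and
  double DDREF removal all raise explicit errors rather than propagating
  NaNs.
* A command-line layer exists because the expected users run case-level
  analyses from a shell; it is a thin veneer over the library functions.

## Known limitations

* No DICOM-RT reader is included: cases enter through the HDF5 container or
  the synthetic generator. Rasterising RT Structure Set contours is planned
  plumbing, not core method.
* The in-field/out-of-field split used for photon risk attribution follows
  the voxel partition by the 5 % surface; organ-level published splits are
  not reproduced exactly from rounded tables.
* Single-patient, single-sex, single-age coefficient table bundled;
  population-level life-table machinery (EAR/ERR projection) is out of
  scope.
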