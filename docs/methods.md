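# Methods

This note documents the models, numerical choices and known limitations of
each stage. Everything stated here is computed by the test suite or the
acceptance script; nothing is quoted from external measurements.

## Synthetic phantoms

**Volume phantom.** The bone is a spherical-cap shell (outer radius 10 mm,
thickness 0.9 mm, cap half-angle 60°) embedded in soft tissue on a
64 × 64 × 40 grid at 0.4 × 0.4 × 0.7 mm spacing — the anisotropy of a
typical craniofacial CT protocol. A single-curvature cap was chosen over a
realistic orbit because every geometric property (mid-surface, defect rim
circumference, voxel membership) then has a closed form to test against,
while still exercising the behaviours that matter: sub-voxel thickness,
partial-volume edges, and curvature gradients that drive stair-stepping.
Partial volume is simulated honestly rather than by blurring: membership is
evaluated on a `supersample`³-fold subdivided grid (default 4³ = 64 samples
per voxel) and averaged, so edge voxels carry fractional occupancy exactly
as a scanner's finite voxel does. Intensities default to bone 700, tissue
40, additive Gaussian noise SD 20 (HU-like contrast; CT numbers for this
anatomy are conventions here, not reproductions). The ground truth returned
alongside is exact voxel-centre membership. A defect is an angular patch
(default 40°) removed around a fixed mid-cap direction.

What the phantom does **not** model: beam hardening, metal artefacts,
scanner PSF anisotropy beyond voxel averaging, intensity inhomogeneity, and
anatomy-scale shape variation. Passing tests therefore demonstrate
correctness of the algorithms under controlled partial-volume and noise
conditions, not clinical-grade segmentation accuracy.

**Stair surfaces.** Printed-surface patches are 4 × 5.3 mm height maps
(7.8 µm lateral spacing, the instrument-class lateral resolution) of
parallel bead ridges: on a surface inclined `slope_deg` (default 45°) to
the build axis, layers of height *h* intersect with along-surface period
*h*/sin(slope). The bead cross-section is a circular arc of peak-to-valley
`bead_amplitude_coeff · h` (default 0.5 — chosen once so the simulated Sa
magnitudes sit in the tens-of-µm range of extrusion-printed PLA). Gaussian
measurement noise (SD 2 µm, the vertical-resolution scale) is added and the
mean plane removed. The construction guarantees the two properties the
texture study relies on: amplitude parameters scale linearly with *h*, and
the dominant spatial period equals the layer spacing. It does not model
bead asymmetry, seam artefacts, elephant-foot, or replica-material fidelity.

All generators draw from one named `numpy` Generator seeded from the spec;
identical seeds give bit-identical outputs.

## Resampling

The BC-family piecewise cubic with B = C = 1/3 is applied separably, four
taps per axis, with replicate (clamp) boundary handling — clamping avoids
ringing at the first/last slice where the series simply ends.
Because B + 2C = 1 the kernel reproduces degree-1 polynomials exactly
(verified to 1e-9) and its four unit-spaced weights always sum to 1
(verified to 1e-12). The output grid starts at the physical position of the
first input sample and steps at exactly the target spacing. Two deliberate
choices:

* The kernel is *approximating* (w(0) = 8/9), so resampling an axis whose
  spacing already equals the target would smooth data to no benefit; such
  axes are skipped, making same-spacing resampling the identity.
* The benefit of isotropic upsampling is measured against a common
  reference: both the anisotropic mask (transported to the fine grid by
  nearest-slice replication) and the interpolated volume's mask are
  compared to fine-grid ground truth with one fixed threshold. On default
  phantoms this Dice rises from ≈0.83 to ≈0.97. Compared each on its own
  grid the numbers are not comparable — the fine grid simply contains
  harder voxels.

## Segmentation

Features per voxel: raw intensity, the mean of the 26-neighbour shell, the
mean of the in-plane 8-neighbour ring, gradient magnitude, and 3³-window
variance. The two ring means deliberately *exclude the centre voxel*:
centred Gaussian smoothing measurably degrades sub-voxel-thin shells (it
mixes the thin bright shell into its own estimate and biases the boundary),
whereas centre-excluded ring means supply noise-averaged context the forest
can combine with the unbiased raw value. All intensity-carrying features
are translation-covariant, so classification is invariant to a constant
intensity offset.

Annotations emulate marking "bone" and "surrounding area": 300 points per
dataset, 20% bone and 80% background with 70% of the background within
3 voxels of the structure. The background emphasis places the 50% majority
vote at a conservative operating point (consistent with the tie-break:
exactly 50/50 votes label background), and the near-structure points teach
the forest the partial-volume boundary. With the multi-dataset protocol
(20 training phantoms, 6000 voxels) the forest's Dice on held-out noisy
phantoms (≈0.983) exceeds the best *oracle* single threshold (≈0.979,
grid-searched against full ground truth) on all eight validation seeds
tried during development — context features correct noise flips at the
partial-volume boundary that no global threshold can.

The iso-value handed to surface extraction is the minimum-error threshold:
the midpoint of the intensity interval minimising total misclassification
between the two labelled classes. With equal class spreads this is the
midpoint of the means; with unequal spreads it shifts toward the tighter
class, as the sweep-oracle test verifies.

## Surface

Marching cubes (scikit-image's Lewiner variant, which resolves the
ambiguous cases) runs on the volume with spacing-aware coordinates, so
meshes are in physical mm. Repair is best-effort and always reports what it
changed: vertex welds (1e-6 mm tolerance, union-find over close pairs),
degenerate faces (repeated indices or area < 1e-14), duplicate faces (same
vertex set, either winding), and winding fixes (faces reoriented for
consistent outward normals).

Decimation is an edge collapse with explicit tolerance guarantees rather
than a quadric-error budget: edges are visited shortest-first; a collapse
tries the midpoint then either endpoint; it is accepted only if (a) no
affected face normal rotates more than the angular tolerance and (b) every
*original* vertex carried by the affected region stays within the chordal
tolerance of the new local surface. Carried originals persist across
passes and are re-verified against the 2-ring face set whenever their
neighbourhood changes, so the final one-sided Hausdorff (original vertices
to decimated surface) provably respects the bound — the test re-measures it
by brute force. Planes collapse to a handful of triangles with zero error;
a fine sphere under a 0.005 mm tolerance barely changes, which is the
tolerance doing its job.

STL is read and written directly (binary: 80-byte header, little-endian
uint32 count, 50-byte facets; ASCII: standard solid/facet grammar) so that
truncation and facet-count mismatches fail with byte offsets.

## Template CAD

Mirroring is an exact reflection with winding flip. Alignment is iterative
closest point with two stages: a cheap point-to-point warm start against
the target vertices, then point-to-surface correspondences with a
*point-to-plane* linearised update — point-to-point Kabsch slides
tangentially at a slow linear rate, while point-to-plane recovers a 5°/0.3 mm
displacement to ~1e-6 mm in a handful of iterations. The convergence
criterion is the RMS improvement falling below the tolerance (default
0.01 mm); the RMS history is non-increasing and the best transform is
always returned. Degenerate (collinear) source samples raise.

The defect boundary is traced automatically: per-vertex distance from the
aligned reference to the damaged surface, the largest connected
super-threshold region, its boundary loop, and a periodic cubic spline.
Offsets (±0.5 mm) are taken in the curve's best-fit plane by polygon
buffering and re-projected to the surface. The template patch is built on a
mesh with an actual open rim: the curve selects the nearest rim loop, a
bicubic polynomial height field over the rim's best-fit plane is
least-squares fitted to the surviving surface within the 2 mm extension
band (rim vertices weighted 5×), evaluated on a triangulated interior grid,
and stitched exactly to the rim vertices — so no new open edges appear and
`repair_mesh` finds zero defects. A bicubic over a defect-sized region of a
10 mm-radius cap deviates from the true sphere by ~0.02 mm; the full-chain
test measures the rebuilt patch against intact ground truth at mean |d| ≈
0.02 mm, inside the ±0.1 mm requirement with margin. "Cut" mode samples the
patch twice as finely and sinks a 0.3 mm-wide band along the boundary by
0.15 mm — same surface elsewhere, different sampling, visualising the
damage extent on a single model.

Closed marching-cubes shells have no rim; in the pipeline the patch is
therefore built on the phantom's mid-surface cap (templates are thin
shells; the mid-surface is the natural carrier), while tracing and
alignment run on the full meshes.

## Slicer

Admissible layer heights are tied to the nozzle as [0.175 d, 0.75 d] —
0.07–0.30 mm for the 0.4 mm nozzle, the working range of stock extrusion
profiles and exactly the span the workflow uses. Plans are contiguous;
fine zones contain exactly `fine_h` layers (the zone's last layer may
overshoot the zone end by less than one fine layer); transitions ramp
geometrically over `ramp_layers` (default 3) on the coarse side; base
regions preceding a zone land exactly on the zone start, and the plan as a
whole lands exactly on the top of the range, in both cases by adjusting
trailing layers at no more than 25% of each layer's nominal height. A
single-layer 25% adjustment cannot always absorb the residual (e.g. a
6 mm span of 0.07 mm layers leaves 0.02 mm), hence the backwards
distribution; total height is conserved to well under ¼ of the minimum
layer height.

Slicing intersects the mesh with each layer's mid-height plane; the
unordered segments are noded and polygonised (1 nm precision snap) and
nested by even–odd depth over face exterior shells, so shells with internal
cavities produce polygons with holes. Estimates model two perimeter
contours at 70 mm/s and 80% grid infill at 200 mm/s, with volume from
contour beads plus infill; travel, heating and acceleration are ignored, so
times are comparative, not absolute — the comparisons (constant 0.3 <
VLH < constant 0.07; VLH under 60% of the fine-constant time when the fine
zone covers ≤ 25% of the height) are what the tests assert. An optional
curvature-adaptive mode proposes fine zones where the base-height cusp
h·|cos θ| would exceed a threshold; explicit zones remain the default.

## Metrology

Deviation maps use exact closest-point distances (KD-tree candidate filter
with a proven bound, equal to brute force) signed along the nominal facet
normal, with max/min/range/mean/SD summaries and the fraction inside the
±0.2 mm band. Optional pre-alignment reuses the ICP at 0.005 mm.

Texture pipeline: least-squares plane removal, then an areal Gaussian
high-pass with 50% amplitude transmission at the 1 mm cutoff
(σ = cutoff·√(ln 2 / 2π²)); a 0.1 mm sinusoid passes within 2%, a 5 mm one
is attenuated below 10%. Sa is the mean absolute height. The Sk family
follows the material-ratio construction: least-slope 40% secant, the
equivalent line extended to 0–100%, Sk its span, Spk/Svk the
area-equivalent triangle heights above/below the intercepts. One
documented refinement: all windows within 0.1% (of the curve's range) of
the least slope contribute and their secant lines are averaged. On generic
surfaces a single window wins and the rule is the standard one; on exactly
symmetric distributions (a pure sinusoid, a two-level surface) the flattest
windows tie at both ends of the curve, and a first-tie rule would produce
an arbitrarily asymmetric Spk/Svk where the surface itself is symmetric.

Rsm averages the mean width of profile elements over six equally spaced
profiles perpendicular to the ridges. A profile element spans successive
upward mean-line crossings; a crossing counts only if the profile rose
above and fell below half the discrimination height (10% of the profile's
peak-to-valley, floored at 1 µm so sub-resolution wiggle is never counted
as structure) and elements narrower than 1% of the profile length merge.
Replica surfaces are negatives: a `replica` flag sign-flips heights on
load (Sa and Rsm invariant, Spk/Svk swap).

Correlation statistics: sample Pearson r, two-sided p from the
t-distribution with n−2 df, and Fisher-z 95% intervals. The grouped form
computes r directly from per-group (mean, SD, n) summaries; for groups of
three it is algebraically identical to expanding each group as
{m−s, m, m+s}, and the tests assert that identity to 1e-12. Feeding in the
published per-layer-height texture summaries reproduces the published
correlations within 0.005 (Sa 0.9934, Spk+Sk+Svk 0.9728, Rsm 0.9717) — the
small residuals are rounding in the printed summaries — and the Fisher
interval of r = 0.9928 at n = 9 is (0.9649, 0.9985) to the printed digits.

## Pipeline and problem sizes

The `run_pipeline` orchestration executes the six stages on the defect
phantom, each stage reading the previous stage's files, with a SHA-256
manifest making reruns byte-reproducible. Default problem sizes were
chosen so a full run takes seconds and the complete validation (including
the 20-phantom segmentation study) finishes in about a minute on one CPU:
64 × 64 × 40 phantom grids, 4³ supersampling, ~6000-face cap meshes,
513 × 680 height maps. Decimation inside the pipeline is off by default —
on marching-cubes output at the 0.005 mm tolerance it removes little and
costs the most time; the operation is exercised on its own fixtures.

## Known limitations

* The cap phantom's symmetry makes azimuthal rotation unobservable; ICP
  validation uses an anisotropically scaled cap for identifiability.
* The defect patch is a single bicubic over the rim plane; defects
  approaching the cap's half-extent or highly non-planar rims would need a
  spline patch with more degrees of freedom.
* Print estimates exclude travel and acceleration; absolute times and
  costs are out of scope by design.
* The DICOM reader handles single-frame CT slices sorted by position —
  enough to ingest a series; no modality metadata beyond spacing/position.
* Segmentation quality figures are phantom-bound; real CT adds artefact
  classes the phantom deliberately omits.
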