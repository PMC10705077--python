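# Methods

`osteovasc` quantifies bone, blood vessels, and metastatic lesions in
four-class 3D label volumes of the kind produced by segmenting
contrast-enhanced micro-CT scans of long bones.  Because no public scan data
accompany this problem, every stage is built around a synthetic phantom
generator with exact ground truth; the phantoms define the study conditions
under which the pipeline is validated.

## Label model

A volume is a dense integer grid (axis order `(z, y, x)`, slices first) over
the vocabulary `{0 background, 1 bone, 2 vessel, 3 metastasis}` with a
physical voxel size in µm per axis (default 3.5 µm isotropic, the resolution
regime of synchrotron micro-CT of mouse tibiae).  All measurements are
expressed in physical units and respect anisotropic spacing.

## Morphometry

**Total volume (TV).**  TV is the volume inside the outer contour of the
bone.  The contour is realized as morphological closing of the bone mask with
a Euclidean ball (default radius 10 voxels at the finest pitch, exposed as a
parameter) followed by 3D hole filling, so the marrow cavity and enclosed
lesions count toward TV.  Two conventions are fixed and used consistently,
including by the brute-force oracles in the test suite:

* *Crop convention.*  The volume is treated as a crop of an axially longer
  bone: the mask is edge-replicated along z during closing and the axial
  faces are capped during hole filling, so the medullary canal counts as
  interior even where it reaches the crop boundary.  Laterally the exterior
  is air (zero padding).  Without the lateral padding, an erosion that cannot
  see out-of-grid background produces spurious exterior pockets at the grid
  faces.
* *Closing via distance transforms.*  Dilation keeps voxels within the ball
  radius of the mask and erosion keeps voxels farther than the radius from
  the dilated set's complement; a one-radius pad is exact for the thresholded
  result.  Radius comparisons carry a small relative slack so that exact
  geometric ties are included deterministically.

**Compartment volumes.**  BV, VV, and Me.V are voxel counts of the bone,
vessel, and metastasis classes times the voxel volume; the normalized
fractions BV/TV, VV/TV, Me.V/TV divide by the TV voxel count.  The phantom
geometry confines all compartments to the bone envelope, so global counts and
envelope-restricted counts coincide.

**Distances and VMI.**  Distance maps are exact Euclidean, voxel-center to
voxel-center, anisotropy-aware (`scipy.ndimage.distance_transform_edt`).  The
vascular-metastasis interdistance VMI is the mean over vessel voxels of the
distance to the nearest metastasis voxel.  With no metastases present, VMI is
a flagged undefined value, never silently zero.  Internally, stages that only
threshold a distance or average it over thousands of voxels (VOI
construction inside the pipeline, treatment-effect regions in the generator,
morphological closing) use ITK's Maurer transform in single precision for
speed; the public `distance_transform` is double-precision exact and is what
the oracle-equivalence tests check.

**Local thickness (V.Th).**  The maximal-inscribed-sphere definition
(Hildebrand–Rüegsegger): the thickness of a voxel is the diameter of the
largest sphere fully inside the mask that reaches the voxel.  Discretely, the
mask surface is taken half a voxel beyond the outermost foreground voxel
centers, so the inscribed radius at a candidate center is its EDT value minus
half the finest pitch, and a sphere reaches a voxel when it comes within half
a voxel of its center.  Under this symmetric convention a single isolated
voxel has thickness of one voxel diameter, and lattice-aligned spheres and
cylinders of radius r voxels are recovered within one voxel of 2r.  Obliquely
oriented tubes read up to about one voxel low — a known property of
EDT-based thickness (the minimum over many surface directions concentrates
the EDT near the continuum radius rather than half a voxel beyond it).
Relative comparisons, which the treatment-effect analysis relies on, are
unaffected.  The sweep paints spheres in order of decreasing radius, scatter
painting around sparse center sets, so each voxel keeps the largest sphere
that reaches it.

**VOI-restricted local metrics.**  The VOI at threshold t is the set of TV
voxels whose distance to the metastasis compartment is strictly below t
(default thresholds 300, 700, 1000 µm; the 700 µm VOI feeds the group
comparisons).  Local VV/TV divides vessel voxels inside the VOI by the VOI
voxel count.  Local V.Th samples the thickness map — computed on the *full*
vessel mask so inscribed spheres are not truncated at the VOI boundary — at
vessel voxels inside the VOI.  A VOI with no vessels yields local VV/TV = 0
and a flagged undefined V.Th.

## Baseline segmentation and Dice

The Dice coefficient 2|A∩B|/(|A|+|B|) is computed per foreground class;
empty-versus-empty is defined as 1.0 (perfect agreement on absence), a case
real cohorts do not meet.

The classical baseline segmenter exists to exercise the evaluation and
downstream stages end-to-end; it is deliberately simple and is *not* a
substitute for learning-based segmentation on real data.  Pipeline: Gaussian
smoothing (1 µm) → threshold into bone and vessel → remove components below
per-class minimum sizes → close the bone mask into an envelope (default ball
radius 30 µm) → label envelope-interior cavities of sufficient size (default
50 voxels), not occupied by bone or vessel, as metastasis.  Auto-thresholds
come from a four-class Otsu on the pooled smoothed intensities, matching the
four attenuation populations (background, marrow≈metastasis, bone, vessel);
a plain hierarchical two-class Otsu proved unreliable because the dominant
background mode absorbs the marrow mode.  Foreground connectivity is
26-neighborhood.

*Scope of validity.*  Metastases carry no contrast of their own and must be
inferred as missing bone.  The cavity-closing inference is well-posed only
when lesion breaches are clearly smaller than the marrow canal and no
trabecular struts subdivide the marrow; on such phantoms (no rods, lesion
semi-axes 10–18 µm) all three classes reach Dice ≥ 0.95.  On the generator's
default geometry (semi-axes 18–38 µm, trabecular rods present) metastasis
Dice drops to roughly 0.8 or below while bone and vessel stay above 0.93 —
which is precisely why the missing-structure problem calls for learned
segmentation on real images.  The calibration-set-size sweep
(`training_size_experiment`) varies how many samples feed the auto-threshold
estimate and reports per-class Dice against a fixed test set.

## Phantom generator

The generator emulates a tibia-like crop: a tapered cortical tube (outer
radius 90 µm, wall 25 µm, 12% taper over the crop), trabecular rods (10 rods
of radius 6 µm), tortuous vessel branches voxelized as swept capsules (8
branches, radii uniform in 7–12 µm, confined to the tube), and ellipsoidal
lesions centered on sampled bone voxels (2 lesions, semi-axes 18–38 µm).
The default grid is 64³ at 3.5 µm — a scaled-down crop of a real acquisition
volume, chosen so that a full multi-cohort power analysis runs on one CPU in
minutes.  Labels compose with precedence metastasis > vessel > bone; a
metastasis voxel is one where bone existed before lesion erosion, which
enforces the missing-bone-only signature (the part of a lesion falling in
marrow is indistinguishable from marrow, as in real images).

Renderings assign per-compartment means (background 0.10 < marrow 0.35 <
bone 0.65 < vessel 0.90; the vessel/bone ordering is configurable), give
metastasis voxels the *marrow* mean, then blur (Gaussian, 2 µm, partial-volume
emulation) before adding Gaussian noise (SD 0.02) — physical point spread
precedes detector noise.

Cohorts replicate a two-time-point (T1/T2), four-arm (P/B/V/C) design with
7 samples per T2 arm.  A group effect can multiply vessel radii by a factor
(default 0.6 for the combined treatment) for branch segments whose midpoint
lies within a stated distance (700 µm) of the lesions, offset the lesion
count, or scale the cortical wall.  Per-sample seeds derive deterministically
from the cohort seed and sample index, so any single sample is reproducible
in isolation.  Ground truth records exact class counts, per-branch radii,
per-segment effective radii with effect flags, and lesion geometry.

What the phantoms do *not* emulate: beam hardening, ring artifacts,
hemodynamically realistic vascular trees, biologically textured lesions, or
intensity inhomogeneity across the field of view.  Tests passing on phantoms
therefore demonstrate correctness of the measurement chain, not segmentation
performance on real scans.

## Statistics

Each group comparison follows the classical small-animal µCT scheme: a
Lilliefors normality test per group, Bartlett's test of equal variances
across groups, then the one-way ANOVA F-test, with significance tiers at
p < 0.05 / 0.01 / 0.001 and no multiple-testing correction by default (a
Bonferroni flag exists).  The Lilliefors p-value is Monte Carlo — the null
distribution of the sup-distance statistic is simulated with the same
estimate-then-compare step at the same n (default 2000 replicates, add-one
rule) — which keeps the test exact at the small group sizes of this design
(n = 7).  Bartlett was chosen as the variance check because it is the
classical companion of ANOVA.  When an assumption check fails the ANOVA is
still computed but carries an `assumptions_met=False` flag and no tier
unless explicitly overridden; no nonparametric fallback is provided.  The
study design runs T1-vs-T2 contrasts on BV/TV, VV/TV, V.Th, and Me.V/TV, and
compares the T2 treatment arms on the 700 µm-VOI local VV/TV and local V.Th.
For two groups the ANOVA F equals the squared pooled-variance t statistic.

Calibration, verified by the test suite: the null rejection rate of both
tests at α = 0.05 lies in [0.035, 0.065] over 2000 simulations, and null
ANOVA p-values are uniform (Kolmogorov distance < 0.05).  Power, verified
end-to-end: across 100 seeded T2 cohorts with the 0.6× local shrinkage in
group C, the local V.Th comparison flags a decrease at p < 0.05 in well over
80% of cohorts, while matched null cohorts flag at about α.

## Numerical and design choices

* Strict `<` for the VOI threshold; ties at the threshold are excluded.
* Distances are voxel-center to voxel-center; surface distances were
  rejected as under-specified for label data.
* Undefined quantities (VMI without metastases, V.Th in a vessel-free VOI,
  constant samples in normality tests) are flagged errors or `None` values,
  never silent zeros.
* Degenerate ANOVA input (zero within-group variance, nonzero between) yields
  p = 0 with an explicit warning.
* Pipeline outputs are CSV (diff-able, inspection-friendly); the run manifest
  records config echo, seeds, and SHA-256 checksums of every output, and
  rerunning a config byte-reproduces the CSVs.
* Volume I/O supports TIFF stacks (ImageJ-flavored spacing metadata),
  MetaImage, NIfTI (µm units), and raw+JSON sidecar; voxel size always
  travels in the header and an explicit override is required when absent.

## Problem sizes

Unit and property tests run on grids up to 32³ against brute-force oracles
(all-pairs distances, direct sphere fitting, shift-loop morphology).  The
end-to-end power analysis uses 64³ phantoms, 4 × 7 samples per cohort, 100
effect cohorts plus 50 null cohorts; these sizes were chosen so the complete
validation runs on a single CPU in roughly ten minutes while keeping every
group comparison at the study's native sample size of 7.
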