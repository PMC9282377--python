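# Methods

`tibiapipe` implements the standard longitudinal micro-CT measurement
pipeline for the mouse tibia — rigid alignment, volume-of-interest (VOI)
selection, densitometry with a 10×4 spatial bone-mineral-content (BMC)
map, trabecular/cortical morphometry, and a voxel-based micro-finite-element
(micro-FE) compression model — together with the precision statistics (CV,
PE, LSC, ICC) used to quantify how reproducible those measurements are when
the operator-dependent steps are repeated. Because no public in vivo scans
accompany the protocol, the package ships a synthetic tibia generator with
exact ground truth, and an in-silico intra-operator experiment that
exercises the entire pipeline end to end.

## Pipeline model and assumptions

**Alignment.** Every image is rigidly registered to a reference (follow-up
scans to the subject's own aligned baseline) by maximizing normalized
mutual information, NMI = (H(A)+H(B))/H(A,B), over the six rigid
parameters. The optimizer is a two-level (shrink factors 4 and 2)
Powell search; the objective uses 64-bin joint histograms over the
foreground bounding box with linear interpolation, and the accepted
transform is applied once with a Lanczos (a = 3) kernel. The registration
optimizer, bin count and window are free choices (only the NMI criterion
and the Lanczos family are fixed by the protocol); they are exposed as
parameters. On default phantoms the optimizer recovers imposed
repositioning to ≲0.4° and ≲0.01 mm; a finer third level at full
resolution was evaluated and rejected — at these noise levels it chases a
noise-biased optimum and degrades the axial rotation estimate.

**Resampling.** The Lanczos resampler is a separable windowed-sinc
(a = 3) with the weights renormalized to unit sum at every sampling phase.
Renormalization matters: a raw windowed sinc has non-unit DC gain and
loses ≈0.8% of the image integral per pass at this scale, which would
masquerade as a mineral-mass error after the two passes a follow-up image
undergoes. With renormalization the integral is conserved to <0.05% over
two passes; integer-voxel shifts and constants are reproduced exactly.

**Smoothing and segmentation.** After alignment a 3×3×3 Gaussian kernel
(σ = 0.65 voxels, normalized to unit sum) suppresses noise. Bone is
segmented at the specimen-specific global threshold, the midpoint of the
background and bone peaks of the smoothed histogram (256 bins, 5-bin
moving-average smoothing). The bone peak is the most prominent maximum at
least 25% of the grey range away from the background mode — the
separation constraint keeps the partial-volume shoulder between the modes
from being mistaken for the bone peak. The fibula is removed by keeping
the largest 2-D component per slice around the tibio-fibular junction and
then the largest 3-D component (26-connectivity, configurable); the
micro-FE mesh additionally applies the strict 6-connectivity rule.

**VOI.** The VOI starts at the first cross-section free of growth-plate
tissue (an operator input; an automated heuristic that finds the band
where the endosteal interior holds no bone is provided as a surrogate) and
spans 80% of the tibia length, L = (z_last − z_first + 1)·voxel. Slice
counts round half-up.

**Densitometry.** TMD = slope·grey + intercept (mgHA/cc); per-voxel
BMC = TMD × voxel volume. Total BMC integrates the *unclamped* calibrated
density over the VOI bone mask dilated by 2 voxels, plus any voxel inside
the per-slice periosteal envelope whose signal exceeds a floor halfway
between the background peak and the threshold. The dilation captures the
support of the resampling and smoothing kernels (so partial-volume mineral
at the bone surface is counted and the integral is conserved); the
envelope-bounded faint term captures sub-threshold trabeculae without ever
re-admitting the excluded fibula; leaving the density unclamped lets
zero-mean background noise cancel instead of half-rectifying. TMD is
averaged over bone voxels only; TV is the per-slice filled (hole-closed)
envelope, BMD = BMC/TV, and per-slice total/bone areas provide the
average/minimum cross-section parameters. The VOI is split into 10
longitudinal sections (remainder slices assigned to the most proximal
sections) × 4 quadrants (anterior centred on +x, then counter-clockwise
medial, posterior, lateral; boundaries at 45° to the axes through the
per-slice bone centroid, half-open bins). Partition labels cover the whole
integration region, so the 40 cells sum to the total BMC exactly (float
tolerance 1e-9 relative).

**Morphometry.** Trabecular VOI: 0.2 mm below the reference slice,
extending 1 mm distally; in-plane ROIs from interpolated polygon contours
or the automated endosteal fallback (filled envelope minus the
boundary-connected cortical shell, eroded 2 voxels). Tb.Th/Tb.Sp use the
Hildebrand–Rüegsegger largest-inscribed-sphere definition (Euclidean
distance transform + exhaustive sphere painting; no pruning — a sphere's
coverage is not subsumed by the sphere that covers its centre).
Tb.N = (BV/TV)/Tb.Th (the ratio convention; the literature names the
parameter but not a formula). Conn.D is β₁/TV with β₁ = β₀ + β₂ − χ; χ
comes from counting vertices − edges + faces − cubes of the voxel cubical
complex, β₀ from 26-connected labelling, β₂ from enclosed background
cavities, and "connectivity around the boundary" is approximated by
edge-replicating one voxel before the Euler count. DA is the ratio of the
longest to the shortest semi-axis of the mean-intercept-length ellipsoid
(1/MIL² fitted by least squares over 128 quasi-uniform directions by
default; deterministic grid-offset test lines at 2-voxel spacing, 0.7-voxel
sampling). Cortical analysis closes each midshaft slice with a round
kernel (10 px at 10.4 µm; scale the radius with voxel size), reports
Tt.Ar (filled periosteal area), Ct.Ar, their ratio, and Ct.Th as the
inscribed-sphere thickness of the closed 3-D stack.

**Micro-FE.** Each bone voxel becomes an 8-node hexahedral element
(trilinear shape functions, 2×2×2 Gauss integration), E = 14 800 MPa,
ν = 0.3. The distal end surface is fully constrained; every
proximal-surface node receives a 0.1 mm axial displacement with
transverse DOFs left free. Apparent stiffness is the summed axial distal
reaction over the displacement. Element strains are evaluated at
centroids, nodal third-principal strains by unweighted incident-element
averaging, and the failure load scales the linear solution so that 10% of
nodes (nearest rank, k = ⌈0.10·N⌉) reach ε₃ = −14 420 µε. The solver is
conjugate gradients with a nodal 3×3 block-Jacobi preconditioner on the
full node-aligned system (Dirichlet rows/columns zeroed with unit
diagonal), warm-started from a linear axial ramp; relative residual 1e-8
by default. Below 60 000 free DOFs a sparse direct solve is used instead.
Units are MPa–mm–N.

**Precision statistics.** CV = sample SD (n−1)/mean per subject;
PE = 100·√(Σ CV²/m); LSC = PE·1.96·√(1/n₁+1/n₂) with n₁ = 1, n₂ = 2, so
LSC/PE = 2.4005; ICC is the two-way random-effects, absolute-agreement,
single-measures coefficient computed from the ANOVA mean squares. The SD
denominator (n − 1 versus n) is not standardized in the source protocol;
with k = 3 repeats the choice is material, so it is explicit and
switchable (`ddof`). A subject whose repeats are all identical contributes
CV = 0 even when the value itself is 0 (no observed variability); a zero
mean with non-zero spread remains an error.

## The synthetic phantom

The phantom is a superellipse (exponent 2.5) cross-section swept along a
bowed centerline: proximal metaphyseal flare, cortical shell thickening
toward the midshaft, a low-density growth-plate band whose distal end
gives the VOI start slice an objective truth, an epiphyseal cap, a
metaphyseal rod lattice (vertical rods on a fixed grid, instantiated only
where the full cross-section fits inside the endosteal core so no
sub-voxel sliver rods arise, connected by full-thickness struts between
adjacent rods and anchored to the cortex just below the growth plate,
above the trabecular VOI), and a fibula rod approaching the tibia to
within a resolvable gap at the junction. Mineral densities (cortical
1100 mgHA/cc with a ±4% axial ripple, trabecular 900, cartilage 60) map
to grey levels through a known linear calibration; Gaussian grey-level
noise (SD 8) is added from one seeded generator — identical spec and seed
give bit-identical volumes. Ground truth records all masks, the noise-free
density field, the VOI start slice, and the exact 10×4 partition BMC.

Two scales are provided. The default spec mirrors the in vivo protocol
(10.4 µm voxels, 16 mm tibia) and is impractical to rasterize routinely;
the `coarse` spec used throughout the tests and the experiment is a
5.2 mm tibia at 0.040 mm voxels with the cross-section scaled less than
the length so the cortical shell stays 2–4 voxels thick and trabecular
rods ~1.9 voxels in radius — the thinnest features that survive
resampling, smoothing and thresholding at that resolution. The anabolic
(treatment) effect scales the cortical thickness profile by
(1+gain)^0.8 and calibrates a small density factor on the noise-free
field so the programmed VOI BMC gain is exact; realizing the gain mainly
as apposition (not densification) means the micro-FE stiffness — which
sees geometry but not tissue density — rises with the mineral mass, as it
does in vivo.

What the phantom does *not* emulate: scanner physics (beam hardening,
scatter, projection noise correlations — noise is additive white),
anatomically realistic trabecular architecture (a rod lattice, not
biological trabeculae, so absolute morphometric values are nominal), soft
tissue background, and growth between time points other than the
programmed cortical gain. Passing tests therefore demonstrate the
*internal* consistency and reproducibility of the measurement chain under
known geometry, not accuracy on real scans.

## The in-silico reproducibility experiment

Five subjects (spec jittered ±3% in size, ±4% in density, ±20% in bow) are
"scanned" at two ages with a per-subject BMC gain drawn from
N(22%, 2²%²) between them, each scan randomly repositioned within ±2°/
±0.1 mm and resampled once (the scan is the repositioned image; ground
truth stays in the canonical frame with the pose recorded). One operator
model then repeats the operator-dependent tasks three times per subject:
registration initialization jitter (±2°, ±0.2 mm), an accepted residual
misalignment after the automatic registration (±1°, ±0.02 mm — operators
visually accept alignment within a tolerance; without this term the
in-silico registration is far more repeatable than a human-supervised one
and the alignment sensitivity of the FE stiffness would be invisible), and
±1 slice of VOI start-slice choice. Baselines register to a common
reference phantom; follow-ups to the same repetition's aligned baseline.
Every repetition runs the full pipeline (FE residual 1e-6 for the batch
runs; the stiffness changes by <1e-4% versus 1e-8) and the report
assembles PE/LSC/ICC per parameter per age, the treatment-effect table,
and BMC recovery.

Recovery compares each repetition's measured total BMC against the
noise-free mineral mass of the *same selected window*, evaluated in the
measured frame (the truth density is mapped through the recorded
transforms). Window choice and accepted misalignment are operator
variability — they are what PE quantifies — so they are excluded from the
accuracy metric.

One scale note: a ±1-slice start jitter at 0.040 mm voxels moves ~1.3% of
the total BMC (the proximal metaphysis is massive), whereas at 10.4 µm the
same one-slice uncertainty moves ~0.1%. Densitometric PE at the reduced
resolution is therefore intrinsically larger relative to the in vivo
protocol; the qualitative ordering (densitometric parameters more
reproducible than FE stiffness, trabecular morphometry least
reproducible) is preserved and is what the acceptance checks assert.

## Numerical choices and degenerate inputs

- Threshold ties are foreground; despeckle removes components strictly
  below 10 voxels (26-connectivity, configurable).
- Largest-component ties break toward the smallest linear voxel index.
- Slice-count rounding is half-up everywhere; slices are half-open
  internally and reported inclusive.
- Empty slices inside a VOI are excluded from per-slice minima with a
  warning; an empty midshaft cross-section is an error.
- MIL directions without intercepts are dropped with a warning; fewer
  than six valid directions is an error.
- Constant images make NMI undefined (error); histograms with fewer than
  two separated peaks request a manual threshold.
- Registration is limited to 2000 objective evaluations per level and
  raises (carrying the last iterate) beyond that.
- A disconnected FE mesh raises before assembly, naming the component
  count; the connectivity filter must run first.

## Known limitations

- Absolute morphometric values at 0.040 mm are strongly
  discretization-affected (2-voxel rods); only their reproducibility, not
  their accuracy, is meaningful at that scale.
- The operator surrogate is a stochastic model, not a human study; its
  jitter magnitudes are declared study conditions.
- The Euler-characteristic boundary treatment (one-voxel edge
  replication) approximates, but is not proven equivalent to, the
  unpublished commercial implementation of "connectivity around the
  boundary".
- The micro-FE model is linear; the failure criterion counts all nodes
  (whether the original criterion counts surface nodes only is not
  documented).
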