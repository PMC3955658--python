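# Methods

## The statistic

Regional homogeneity is operationalized as Kendall's coefficient of
concordance (KCC) among the time series of a spatial neighborhood. For K
series of length n, each series is converted to temporal ranks (average
ranks for ties) and

    W = 12 S / ( K² (n³ − n) − K Σⱼ Tⱼ ),

with S the sum of squared deviations of per-frame rank sums from their mean
and Tⱼ the tie correction Σ(t³ − t) over tie groups of series j. The tie
correction is always applied: filtered BOLD rarely ties, but integer-valued
or degenerate synthetic inputs do, and exactness on those inputs is what
the test suite relies on. If every series in a neighborhood is constant the
denominator vanishes and the vertex is flagged undefined (NaN) rather than
forced to 0/0; undefined vertices are excluded from averages and never
enter cluster formation. Computed values may exceed [0, 1] only by float
error (≤ 1e−9, clipped); anything larger raises.

Surface maps evaluate W for every vertex at once: ranks and tie terms are
computed per vertex series, and neighborhood sums are accumulated through a
sparse membership matrix. This is algebraically identical to evaluating the
scalar statistic per neighborhood (the test suite checks agreement to
1e−12 against a brute-force loop) but runs in milliseconds on meshes with
hundreds of vertices.

### Neighborhood systems

* **2dReHo** — closed one-ring: the vertex plus its edge neighbors, 7
  series at a regular degree-6 vertex.
* **2dReHo2** — closed two-ring: one-ring plus the edge neighbors of its
  members, 19 series where the whole one-ring is regular.
* **3dReHo** — the voxel's 3×3×3 cube, 26 neighbors plus the center.

Icosphere meshes (and real spherical cortical meshes) contain twelve
degree-5 vertices; there the actual one-ring (6 series) and two-ring (16
series) are used, and degree-6 vertices adjacent to a pentagon have 18
two-ring members. Using the true ring whatever the degree keeps the
statistic defined everywhere and matches the "nearest neighbors on the
mesh" reading. Volume masks shrink K at edges instead of zero-padding, so
edge voxels are never contaminated by out-of-mask values; voxels whose cube
retains fewer than two in-mask members are undefined.

No medial-wall or other mask is excluded by default; every summary and the
group model accept an optional vertex mask.

## Surfaces and smoothing

The analysis space is any triangulated mesh; tests and synthetic cohorts
use subdivided icosahedra (10·4^s + 2 vertices, closed, Euler
characteristic 2), which share the degree-5/degree-6 structure of standard
spherical cortical meshes. Vertex areas are barycentric (one third of each
incident triangle), so they sum exactly to the surface area and define the
measure used for mass conservation and cluster extents.

Smoothing is explicit heat diffusion: one step moves
τ/aᵥ · Σᵤ cᵤᵥ (xᵤ − xᵥ) into vertex v, with symmetric edge conductances
cᵤᵥ = (aᵤ + aᵥ)/2 and τ at half the explicit-Euler stability limit.
Because each edge flux is antisymmetric, Σ aᵥxᵥ is conserved to machine
precision at every step, constants are fixed points, and the operator is
linear. The iteration count for a requested FWHM is calibrated empirically:
a delta input at a regular vertex is diffused step by step, the kernel
profile is shell-averaged over graph-geodesic distance, and the step count
whose measured full width at half maximum best matches the request is used.
The calibration is shipped as a utility (`calibrate_smoothing_iterations`,
`empirical_smoothing_fwhm`). A kernel narrower than the inter-vertex
spacing cannot be realized by neighbor averaging; calibration then returns
zero steps (identity), the closest achievable kernel. On the 642-vertex
icosphere at radius 100 mm the spacing is ≈15 mm, so the conventional 6 mm
kernel resolves to the identity there — smoothing becomes substantive on
finer meshes or for wider kernels. Maps are smoothed after the concordance
computation, never the time series.

## Preprocessing chain

Default order, each step a pure function:

1. **drop** — remove the first 5 volumes (scanner equilibration);
2. **normalize** — scale the whole 4-D series so the grand mean is exactly
   10,000;
3. **nuisance** — per-vertex OLS against an intercept, the WM and CSF mean
   series, and the Friston-24 motion expansion (6 parameters, their
   one-frame lags zero-padded at the first row, and both sets squared);
4. **bandpass** — 0.01–0.1 Hz zero-phase 4th-order Butterworth
   (forward–backward); an ideal FFT filter is available as an option;
5. **detrend** — projection removing polynomial trends up to order 2.

Detrending after band-pass is unusual but kept as the default ordering;
the order is a configuration knob and the executed order is logged.

Because the regression precedes the temporal filtering, naively filtered
residuals would lose their orthogonality to the regressors. The chain
therefore conditions the regressors on the adjoint of the later temporal
operations: with O the composition of the post-regression steps, the data
are regressed on Oᵀx, which makes the final series O·r exactly orthogonal
to the raw regressors (⟨O r, x⟩ = ⟨r, Oᵀx⟩ = 0). Oᵀ is obtained by pushing
the identity matrix through the same steps, a few milliseconds at
n ≈ 200 frames. Near-constant regressor columns (for example squares of
tiny motion parameters) that vanish under filtering are dropped from the
design.

Framewise displacement follows the displacement-sum convention:
FDₜ = Σ|Δtranslation| + r·Σ|Δrotation| with head radius r = 50 mm, and
rmsFD is the root mean square of FD over the run. Motion traces are
trimmed in step with dropped volumes.

Volume-to-surface projection applies the inverse affine to vertex
coordinates and samples each frame by trilinear interpolation; every vertex
must fall inside the field of view, and offending vertices are listed.

## Synthetic cohorts

The generator emulates a single-site 3 T acquisition — TR = 2 s, 212
volumes — and a case-control design with 33 patients and 32 controls by
default. Vertex v of a subject receives

    yᵥ(t) = λᵥ s_patch(v)(t) + (1 − λᵥ) εᵥ(t),

where s_p is one shared AR(1) series per local patch, εᵥ is independent
AR(1) noise (lag-1 autocorrelation 0.4 for both), and λ is the coherence
dial. Patches tile the mesh by greedy two-ring coverage from a seeded
random vertex ordering — deterministic and mesh-agnostic. λ maps
monotonically to W (verified over a λ grid): λ = 0 gives independent
series (E[W] ≈ 1/K), λ = 1 identical series within a patch (W = 1).
Background coherence defaults to λ₀ = 0.55, which puts the within-patch
neighbor correlation near 0.6 — the range typical of band-passed cortical
BOLD — and one-ring W of patch-interior vertices in the mid-0.6s; because
one- and two-ring neighborhoods straddle patch boundaries, the global map
means land lower (≈0.4 for 2dReHo, ≈0.25 for 2dReHo2), with the
characteristic ordering 2dReHo > 2dReHo2. Inside a designated effect
region λ takes a group-specific value, so a patient deficit is injected
with known location and size.

Each series is z-scored and mapped to baseline 1000 ± amplitude 10
(≈1 % fluctuation), making intensity normalization meaningful. A WM-like
and a CSF-like AR(1) series are weakly coupled (weight 0.05) into every
vertex and provided as nuisance inputs. Motion is a 6-parameter random
walk; the default step SD of 0.03 mm (rotations scaled by the 50 mm radius
convention) yields rmsFD ≈ 0.15 mm, matching a low-motion adult cohort.
Covariates mirror a mid-life depression sample: age ~ N(34.4, 10.4),
education ~ N(13.5, 3.0) years, registration-cost proxy ~ N(0.60, 0.05),
male proportion 0.4; patients additionally carry HRSD ~ N(20.2, 3.2),
exponential illness duration (mean 6 months) and a consistent onset age.
Clinical scores are generated independent of the coherence effect, so the
expected clinical correlations are null.

Cohort generation is a pure function of (mesh, spec): per-subject
generators are spawned from the spec seed, and the same spec reproduces
bit-identical data.

What the generator does **not** emulate: spatial hemodynamic point-spread,
slice-timing and motion artifacts in the data themselves (motion feeds only
the regressors and rmsFD), susceptibility dropout, anatomical variability,
and any real cortical geometry. Passing tests therefore demonstrate the
correctness and calibration of the statistics under a known generative
model, not robustness to every artifact of real acquisitions.

## Group statistics

The group model is a main-effects ANCOVA fit per vertex by OLS:
ReHo ~ intercept + group + age + sex + education + mcBBR + rmsFD, with
patients coded 1 and sex coded M = 1 / F = 0. The group coefficient's
t-statistic (df = N − 7) with its two-tailed p is the comparison. A
rank-deficient design raises an error naming the columns. Cluster
formation takes vertices with uncorrected p below 0.01, splits them by
coefficient sign, and finds connected components over mesh edges; extent is
reported both in vertices and in summed vertex area (mm²), with area the
primary metric because it is mesh-resolution independent.

Familywise error is controlled by the maximum-statistic permutation
method with Freedman–Lane residualization: the maps are regressed on the
nuisance covariates only, the residual rows are permuted across subjects
under a seeded generator, the covariate fit is re-added, the full model is
refit, and the maximum cluster area — pooled over both signs and the whole
surface, the conservative whole-cortex reading — is recorded per
permutation. The corrected p of an observed cluster of extent e is
(1 + #{perm max ≥ e}) / (n_perm + 1); including the observed statistic
makes the p-value valid by construction, with attainable floor
1/(n_perm + 1) (a warning is recorded when that floor exceeds alpha).
Corrected p is monotone non-increasing in extent by construction. The
empirical familywise false-positive rate on null cohorts sits at the
nominal 5 % level (checked over hundreds of replicates in the acceptance
suite). A permutation scheme was chosen over parametric
smoothness-simulation corrections because it is assumption-light,
self-contained, and its error control can itself be tested.

Scalar comparisons use the pooled-variance two-sample t-test (Welch as an
option) and the Pearson chi-square (without continuity correction) for the
2×2 sex table. Correlation analyses report Pearson r with the
t-approximation p; the cluster-level correlations use the cluster-mean
ReHo of the top significant negative cluster (cluster mean rather than
peak vertex — the less noisy summary).

## Determinism and problem sizes

Every stochastic stage consumes an explicit seed; the full pipeline is a
pure function of its configuration, and one configuration run twice
produces byte-identical numeric artifacts (timings go only to the log, and
the provenance sidecar echoes paths). Numeric text outputs carry full
double precision; GIfTI floating payloads are single precision, the
format's conforming type.

The shipped calibration checks run at desk scale, chosen to estimate each
property with useful precision in minutes: null p-value uniformity pools
100 replicate 10+10 cohorts on the 642-vertex icosphere at 100 frames;
familywise-error control uses 200 null replicates with 200 permutations on
the 162-vertex icosphere at 60 frames; effect recovery runs the full chain
on ten seeded 15+15 cohorts at 212 frames with ROI coherence 0.30 vs 0.15.

## Known limitations

* Geodesic distances for smoothing calibration are graph-shortest-path,
  not exact geodesics; on near-uniform icospheres the difference is well
  below one edge length.
* The smoother realizes kernels only at the resolution the mesh allows;
  sub-spacing FWHM requests resolve to the identity.
* Surface ReHo at degree-5 vertices uses fewer series than at regular
  vertices, so the null level of W varies slightly across the twelve
  pentagon vertices (E[W] ≈ 1/K).
* The ANCOVA is a fixed-effects, single-site model; no FDR, TFCE or
  mixed-effects alternatives are provided.
* The synthetic generator's patch structure imposes artificial coherence
  boundaries; global map means depend on the patch scale and should not be
  compared numerically with real-data global ReHo.
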