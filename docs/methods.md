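# Methods

This note documents the models, conventions and numerical choices behind
`anewall`, what the synthetic generators do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Units and grid conventions

Lengths in mm, velocities and VENC in m/s, stresses in Pa, flow rates in
ml/s, time in s (phase spacing quoted in ms). A happy consequence of this
mix: `m/s × mm² = ml/s` numerically, so plane integrals need no conversion
factors. Grids are cell-centred, isotropic, right-handed, array order
(x, y, z) with the cardiac phase as the leading array axis; voxel (i, j, k)
sits at `origin + spacing·(i, j, k)`.

## Synthetic world

The generators reproduce the acquisition conditions the package targets:
0.5 mm isotropic voxels, 21 cardiac phases at 49 ms (1.029 s cycle,
emulating a 1 Hz trigger on that grid), VENC 1.1–1.2 m/s, and a
glycerine/water blood analogue with ρ = 1142 kg/m³, ν = 4.67·10⁻⁶ m²/s.

**Waveform.** The pulsatile internal-carotid-like inlet waveform is a fixed
band-limited shape: a von Mises systolic bump (κ = 4, peak at 12% of the
cycle) truncated at 8 harmonics with a Lanczos σ-taper (which removes the
truncation ripple, keeping the systolic maximum unique), mean-rescaled to
the requested Q̄. The systolic peak/mean ratio is fixed at 1.65, mid
physiological range. The original study's exact inlet waveform is not
tabulated anywhere we can read it from, so only its mean, period and
qualitative single-peak shape are emulated — a deliberate limitation.

**Flows.** Steady Poiseuille (`u = 2Q/(πR²)(1 − r²/R²)`, wall shear
4μQ/(πR³)) and pulsatile Womersley flow. The Womersley profile per harmonic
n with complex flow amplitude c_n is

    u_n(r) = (c_n/πR²) · (1 − J₀(Λ_n r/R)/J₀(Λ_n)) / (1 − 2J₁(Λ_n)/(Λ_n J₀(Λ_n))),
    Λ_n = i^{3/2} α_n,  α_n = R√(nω₀/ν),

normalised so each harmonic's cross-section integral reproduces exactly its
share of Q(t); the closed-form wall shear is the corresponding Bessel
derivative. Both attach their ground truth (wall shear series, Q(t), an
analytic point sampler) to the generated field. Fields are axial and
x–y-dependent only, hence exactly divergence-free.

**Geometry.** The tube phantom is a structured cylinder mesh (wall/cap face
labels, analytic centerline). The aneurysm phantom fuses a sphere of radius
a at neck radius b onto the tube: the sphere centre sits √(a²−b²) outside
the wall plane, so spherical-cap formulas give exact neck/sac ground truth
(cap height a + √(a²−b²)). The union surface is extracted by marching cubes
from a log-sum-exp smooth-min of the two signed distances (0.25 mm fillet) —
a hard `min` produces a pinched crease that breaks watertightness, and a
small fillet is anatomically more plausible anyway. Meshes are cleaned
(coincident vertices merged, sliver faces dropped) so that topology survives
format round trips. A sac with `a > 2·r_tube` and a near-hemispherical neck
protrudes through the far tube wall; the generator warns and the cap
formulas remain exact even though the fused surface is then degenerate.

**Acquisition model.** Magnitude: constant signal A inside the lumen, A/10
outside, i.i.d. Gaussian noise σ = A/SNR per cardiac phase. Velocity: each
component encoded as phase π·v/VENC with Gaussian noise
σ_v = (√2/π)·VENC/SNR (the standard magnitude-to-phase noise propagation,
which makes the VNR definition self-consistent), wrapped into (−π, π] and
decoded back. No k-space, coil, or compressed-sensing artefact modelling —
noise is added in image space, so a green test establishes correctness of
the post-processing chain, not robustness to reconstruction artefacts.

## Preprocessing

**Temporal unwrap.** Walking forward from a diastolic baseline, a raw step
between consecutive phases beyond +VENC subtracts 2·VENC from all
subsequent samples of that voxel/component (and conversely). The baseline
is operationally "the phase with minimum spatial-mean speed", but aliased
voxels fake low speeds around systole, so the implementation first locates
wrap events (steps beyond VENC) and restricts the candidate baselines to
the phases cyclically farthest from any event — with no events this reduces
to the plain minimum. Detectability has a sharp limit: a wrap crossed with
a true inter-phase step smaller than VENC always produces a detectable
(>VENC) acquired step; a wrap jumped together with a large true step does
not. The implementation therefore checks cyclic consistency — one full
cycle must wind back to zero net correction — and flags voxels with nonzero
winding as unresolved rather than guessing.

**Normalized median test.** Per voxel, phase and component, with m the
median of the up-to-8 in-plane lumen neighbours (plane orthogonal to the
dominant flow axis; configurable) and r_med the median neighbour residual,
flag when max over components of |v − m|/(r_med + ε) > 1 and replace by m.
ε defaults to 0.05·VENC as the acquisition noise floor. Voxels with fewer
than 3 valid neighbours are left untouched and listed. Note that at
detection threshold 1 the test is aggressive on strongly curved profiles
(it flags a third of the voxels of a 3-voxel-radius parabolic jet and
biases integrated flow a few percent high); this is the documented
behaviour of the method at that threshold, not a defect of the
implementation, which matches a brute-force oracle voxel-for-voxel.

**Lumen masking.** Voxel centres inside the (optionally rigidly
transformed) watertight surface, by per-column ray parity.

## Geometry

**Centerline.** Voxelised interior (0.25 mm) → Euclidean distance
transform → Dijkstra shortest path under edge cost `step/(distance + ε)`
(ε = half a voxel) → spline smoothing → gradient-ascent refinement onto the
smoothed distance ridge, restricted to the plane normal to the local
tangent and tapered to zero within 1 mm of the endpoints (near an opening
the ridge bends toward the cut plane). The local vessel diameter is twice
the exact point-to-triangle distance to the wall; within ~1.5 mm of an
opening it reflects the cut plane, so consumers (e.g. the inlet parent
diameter) read it at the first station clear of the end.

**Registration.** Maximise the mean systolic-speed-image intensity sampled
(cubic B-spline) at fixed interior points of the surface, over 3 Euler
angles + 3 translations with L-BFGS-B and numerical gradients. On an
axisymmetric phantom the rotation about the vessel axis is a gauge freedom;
the identifiable components are recovered to ~0.03 mm / 0.03° in the tests.
A flat objective (featureless image) or optimizer failure returns
best-so-far with a warning rather than raising.

**Sac isolation.** Faces whose centroid lies within (D_vessel(s*) + 1 mm)/2
of the nearest centerline point s* are removed ("diameter + 1 mm around the
centerline", read as a diameter for dimensional consistency); the sac is
the largest remaining connected component (others reachable by rank) and
the neck loop is its ordered boundary. The neck produced by this rule is
the cut at the removal radius, not an anatomical neck — on the sphere
phantom the resulting loop is a non-planar ring whose area-equivalent
diameter is ~10% below 2b; the spherical-cap area ground truth is met
within a few percent.

**Neck plane and morphometrics.** Total least squares (principal axes;
smallest-variance axis is the normal). Conventions, each a documented
choice because no formula is universal: perpendicular height = max signed
distance of sac vertices on the sac side of the neck plane; max height =
max distance from the neck-loop centroid; max width = diameter of the
convex hull of the sac projected onto the plane; neck diameter =
area-equivalent diameter of the projected neck loop; aspect ratio =
perpendicular height / neck diameter; volume = sac closed by the planar
neck cap via the divergence theorem (with the origin on the cap, the cap
fan contributes zero). Under these conventions two of the three published
aneurysm aspect ratios (1.24, 1.35) follow exactly from the corresponding
printed heights and neck diameters; the third (0.88 vs 6.99/11.62 ≈ 0.60)
does not, and we deliberately do not force agreement — the original
convention for that case is not recoverable from the text.

## Flow rates

Plane flow = Σ v_n · w · Δ² on a 0.1 mm in-plane raster, v_n the normal
velocity interpolated from the voxel grid, w the fraction of each pixel's
4×4 subpixels inside the lumen contour (the surface/plane intersection
polygon). Interpolation is cubic B-spline by default: trilinear
interpolation of a parabolic profile from 0.5 mm voxels is biased ~2% low,
while the cubic reproduces it to ~0.7%; the trilinear kernel remains
available (`interp_order=1`) and is used in the raster-convergence test.
Stations within 1 mm of a centerline end are excluded by the pipeline —
planes on the cut faces clip the cross-section. Systole is defined as the
phase of maximum inter-plane mean flow. Re_m = 4Q̄/(πνD) and
α = (D/2)√(2πf₀/ν) with SI conversions internal.

## Wall shear stress

Normals: per-point PCA of the 20 nearest wall points, smallest-variance
axis, oriented inward by a 0.1 mm probe against the lumen; ambiguous points
are excluded. WSS: velocities sampled at ξ₃ = 0, 0.5, 1.0, 1.5 mm along the
inward normal, wall sample forced to zero; each tangential component is
differentiated at the wall through the unique cubic through the 4 samples
(finite-difference weights [−11, 18, −9, 2]/(6·0.5 mm)), so polynomial
profiles up to degree 3 — including Poiseuille — are differentiated
exactly. Tangential derivatives of the normal component vanish by no-slip.
Time quadrature for TAWSS and OSI is the rectangle rule on the uniform
phase grid (periodic cycle). OSI at a vertex with zero shear-magnitude
integral is reported as NaN, not 0 or 0.5 — dead-flow vertices should not
fabricate extremes. On the 0.5 mm acquisition grid the estimator is biased
low (trilinear sampling flattens the near-wall profile); the bias shrinks
monotonically with grid refinement and is within 2% at 0.1 mm — the test
suite asserts exactly this resolution behaviour.

## Quality metrics

SNR difference method per slice k: mean over the vessel ROI of
(S_i + S_{i+1}) over √2 × stddev of (S_i − S_{i+1}), averaged over slices;
the phase pair is chosen among consecutive pairs whose lumen-mean speeds
differ ≤ 1% (diastole), taking the highest-SNR pair, with a flagged
minimum-difference fallback. VNR = (π/√2)(mean |v̄|/VENC)·SNR with v̄ the
time-averaged velocity over the lumen. Slices run along the third grid axis
by default (configurable).

## Numerical/degenerate-input policy

Collinear point sets (neck plane, PCA neighbourhoods) raise or flag rather
than return arbitrary axes; empty sacs return an explicit "empty" status;
zero difference-stddev (noiseless identical magnitudes) raises naming the
slice; non-watertight surfaces are rejected wherever containment is needed;
ties in the phase-pair selection break to the lowest index.

## Limitations

* Noise is image-space Gaussian: no reconstruction, eddy-current or
  Maxwell-term phase errors (assumed corrected upstream).
* The synthetic sac carries no internal flow model — the sac case tests
  geometry, masking and the WSS machinery on near-stagnant noise, not
  impinging-jet hemodynamics; parent-vessel flow is the quantitative oracle.
* Newtonian rheology throughout; shear-thinning behaviour at low shear is
  out of scope.
* The centerline is a medial shortest path, not a full vascular-tree
  extractor; it expects two endpoints on openings of a single channel.
* Registration assumes an initial alignment within a few mm/degrees and a
  bright-lumen speed image; it is a local optimiser.
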