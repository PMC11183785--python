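# Methods

This note documents the models, numerical choices and limitations behind
`cereflow`, in the order the pipeline runs.

## Data model and conventions

A 4D flow dataset is a magnitude series `(phase, z, y, x)` plus a velocity
series `(phase, component, z, y, x)` with components ordered (x, y, z) in
m/s, on one voxel grid. Spacing is millimetres in (z, y, x) order; world
coordinates are `index * spacing` (scanner affines are out of scope — the
phantoms define their own frame, and masks are always grid-aligned with
their flow volume). The canonical container is a single HDF5 bundle
(`/magnitude`, `/velocity`, metadata as attributes); NIfTI import/export is
provided per component with a YAML sidecar, converting NIfTI's x-fastest
axis order on read. Integer-stored velocities are interpreted as 12-bit
signed phase encodings, `v = stored / 4096 · VENC_high`; this convention is
a design choice, since stored encodings vary by vendor.

Heart rate is estimated as `60000 / ((n_phases + 1) · TR_ms)` bpm: the
reconstructed phases tile the cardiac cycle, but the trigger window
discards roughly one TR, so the period exceeds `n_phases · TR` by one TR.

## Preprocessing

*Noise mask.* A voxel is signal-bearing when its time-averaged magnitude
exceeds the `noise_quantile` (default 0.35) quantile of the whole-volume
distribution. The default suits volumes where roughly a third of the field
of view is air; it is a config key, not a constant. A constant-magnitude
volume makes the threshold meaningless; the mask degenerates to all-ones
with a warning rather than an error, so synthetic edge cases keep flowing.

*Static tissue.* Signal-bearing voxels whose per-component temporal
velocity standard deviation stays below `0.05 · VENC_high` (config key
`static_std_frac`). This avoids any anatomical template.

*Eddy-current correction.* Residual gradient-induced phase offsets appear
as a temporally constant, spatially smooth velocity bias. Per component, a
polynomial of total degree `eddy_poly_order` (default 2) in normalized
voxel coordinates is least-squares fitted to the temporal-mean velocity
inside the static mask and subtracted from every phase. Coordinates are
scaled to [-1, 1] for conditioning; the fit requires at least 10× as many
static voxels as coefficients and rejects rank-deficient designs. The
operation is idempotent to machine precision, which the tests assert.

*Dual-VENC anti-aliasing.* Velocities beyond ±VENC_low wrap by multiples
of 2·VENC_low. Each low-VENC value is replaced by the replica
`v_low + 2·VENC_low·k` closest to the alias-free high-VENC measurement,
ties broken toward smaller |k|. The output is congruent to `v_low` modulo
2·VENC_low by construction, preserving the low-VENC noise advantage.
Because the noiseless replicas sit exactly half a period away from the
decision boundaries, replica selection tolerates high-VENC noise up to a
large fraction of VENC_low; at σ = 0.02 m/s and VENC_low = 0.5 m/s,
misselection is practically impossible, which is what the recovery test
measures.

## PCMRA

The pseudo-complex difference weighting (see README for the formula) is
evaluated per phase per voxel, since the speed varies over the cycle. The
printed piecewise form is the default, including its jump at
`v = (2/3)·VENC`; fidelity comes first. Note the weighting
`v · sin(π v / VENC)` is not monotone all the way to the cutoff — it peaks
at `v ≈ 0.646·VENC` and dips slightly before the fallback branch takes
over; the monotonicity test therefore covers `[0, 0.6·VENC]`. The
`normalized` variant `I · sin(π · min(v, VENC) / (2·VENC))` is smooth,
bounded by the magnitude, and saturates at VENC; it exists for users who
prefer a continuous weighting over the literal piecewise one.

## Phantoms

The generator emulates exactly the structure the pipeline assumes, nothing
more: tubes with circular cross-section, radius profile
`R(s) = R₀·(1 − g·exp(−(s−s₀)²/(2σ²)))` (g = fractional diameter
reduction, σ = `stenosis_width_mm`), parabolic (or plug) axial velocity
with `v_max(s) = v_max·(R₀/R(s))²` so the volumetric flow
`Q = v_max·π·R₀²/2` is conserved along the tube. Units: v in m/s, R in mm,
hence Q in ml/s with no conversion factor (1 m/s·mm² = 1 ml/s). Curved
axes are quadratic Béziers with analytic tangents. Bifurcations override
daughter inlet velocities so `Q_parent = Q_d1 + Q_d2` holds exactly at the
stated split fraction.

The magnitude scene is three-valued: air 5, a central tissue ellipsoid 50,
lumen 100 (arbitrary units). Truth masks use the voxel-center-in-lumen
rule — no partial-volume labels — so Dice oracles are unambiguous. The
cardiac waveform is a raised-cosine systolic peak over the first 35% of
the cycle, mean-normalized to 1, so the temporal-mean flow equals the
tube's nominal Q; it mimics pulsatility without a physiological model. Noise is
Gaussian: magnitude σ = lumen_magnitude / SNR, velocity
σ = √2/π · VENC_high / SNR (the standard phase-noise relation). Velocity
aliasing is simulated by `((v + VENC) mod 2·VENC) − VENC`.

Default acquisition metadata mirror a clinical intracranial dual-VENC
protocol: VENC_low 0.5 m/s, VENC_high 1.0 m/s, TR 50 ms.

The random training-set generator lays out 2–6 straight-or-curved tubes
per case (radii 1.2–2.5 mm, optional stenoses of grade 0.3–0.7), capping
the summed analytic tube volume at 9% of the grid so the foreground
fraction stays in the 0.1–10% band typical of vascular masks. Cases get
independent child seeds from one root seed, so sets are reproducible and
pairwise distinct.

What the phantoms do *not* contain — and hence what passing tests do not
show about clinical data: no Navier-Stokes realism (no post-stenotic jets,
recirculation or turbulence), no wall motion, no partial-volume or phase
dispersion effects, no background phase errors beyond the synthetic
polynomial, no anatomical variability of the Circle of Willis. Results on
phantoms bound discretization and algorithmic error only.

## Segmentation network

The dense-block 3D U-Net follows the architecture described in the README.
No deep-learning framework is used: convolutions are im2col GEMMs in
float32 with hand-derived backward passes (verified against float64 finite
differences in the tests), batch normalization runs per channel over the
full volume (batch size 1), and optimization is Adam with default moments
— the training recipe fixes only the learning rate, batch size and epoch
count, so Adam's moments are a design choice. Depth (levels), growth rate
and stem width are config-exposed defaults rather than fixed constants,
and the desk-scale experiments use a miniature configuration
(2 levels, growth 4, stem 4, ~3.6k parameters) on 64×64×32 phantoms, where
one training epoch over 8 volumes takes a few seconds on one CPU. The
capacity experiment trains 40 epochs at learning rate 3e-3 — a rate sized
for the miniature network; the clinical-scale default remains 1e-4 — and
reaches training Dice ≈ 0.96 and held-out Dice ≈ 0.95 against generator
truth.

Inputs are standardized per volume (zero mean, unit variance) and
center-cropped or zero-padded to the fixed network dimensions (extra voxel
removed from, or added to, the high-index side on odd differences); no
patching, no augmentation. Masks are the per-voxel argmax with exact
probability ties assigned to background. Training keeps the
best-validation-Dice parameters when a validation set is given. All
randomness (init, dropout, shuffling) flows from explicit seeds; identical
seeds reproduce losses bit-for-bit on one machine.

## Agreement metrics

Dice is set overlap on voxel labels (defined as 1 when both masks are
empty). Hausdorff and ASSD operate on boundary voxels — mask voxels with a
face-adjacent background neighbor, grid-edge voxels included — at
voxel-center world coordinates, so they scale with spacing and read as mm.
This is the standard "surface distance" reading; a full-set Hausdorff is
available behind a flag. Distances use KD-trees and are tested for exact
agreement with O(|X|·|Y|) all-pairs oracles. The symmetric Hausdorff is
used throughout.

## Statistics

Bland-Altman statistics are relative: `d_i = 100·(test_i − ref_i)/ref_i`
against the designated reference observer (not the pair mean), bias is the
mean and LOA `1.96 · sample SD` of the d_i. ICC is the two-way
random-effects, absolute-agreement, single-measurement ICC(2,1), computed
from ANOVA mean squares; the choice of variant is a convention, made
explicit here, and cross-checked against an independent implementation in
the tests. Group comparisons gate on Shapiro-Wilk normality (p > 0.05 in
both groups → unpaired t-test, otherwise Mann-Whitney U), significance at
p < 0.05. Degenerate ICC input (zero variance everywhere) returns 1 with a
warning rather than NaN.

## Centerlines and flow quantification

Thinning-based skeletonization proved unreliable for voxelized tubes with
even-width cross-sections, so centerlines are extracted by penalized
geodesics: the voxel graph (26-adjacency) is weighted by Euclidean step
length divided by the squared distance-to-boundary at the step midpoint,
making shortest paths hug the vessel axis. Branches grow farthest-point
first from the deepest voxel; a candidate branch is accepted while it is a
genuinely elongated structure (path length > 2× the maximal
inscribed-sphere radius it traverses), which makes a solid sphere collapse
to a single short branch instead of sprouting radial spokes. The voxel
chains are decomposed at degree-≥3 junction clusters, trimmed where the
local radius falls below 70% of the chain median (the centerline within
one radius of a vessel cap is ill-defined and drifts toward cap corners),
smoothed by a window-5 moving average, refined to sub-voxel accuracy by
iterated perpendicular-slab centroids, extended along the end tangents
back to the caps, and uniformly resampled at one-voxel arc steps. On a
straight noiseless tube the recovered axis deviates from truth by under
0.05 voxels and the chain length is within 1% of the true length.

Analysis planes are placed every 0.25 mm of arc length (the default
follows the clinical protocol), normals parallel to local tangents. Planes
within 2 mm of a junction are excluded (the exclusion itself is protocol;
the radius is a configurable choice) and planes within 1.5 mm of a vessel
end are excluded because the cap truncates the cross-section. Per plane,
mask and velocities are sampled on an in-plane grid at `min(spacing)/4` by
trilinear interpolation; the lumen is the 8-connected region containing
the plane center after thresholding the interpolated mask at 0.5, which
prevents capturing an adjacent vessel crossing the plane. Area is pixel
count × pixel area; flow per phase is `Σ v·n dA` (ml/s); peak velocity is
the speed maximum over lumen pixels and all phases (a through-plane-only
variant exists behind a flag; whether clinical peak velocity is systolic
or all-phase is ambiguous, and on phantoms the two coincide at the
waveform peak). Per-vessel summaries take medians over planes, flows as
magnitudes so plane orientation cannot flip signs. The flow conservation
error uses flow magnitudes for the same reason.

Numerical behavior at 8–10 voxels per diameter (noiseless): area bias
≈ +1.5% (trilinear mask interpolation at threshold 0.5 slightly dilates
the lumen), flow bias ≈ −1.3% (linear interpolation under-integrates the
concave parabolic profile), peak velocity bias ≈ −2% (the sampled maximum
misses the exact axis unless it threads voxel centers). A severe (g = 0.7)
stenosis throat at 0.4 mm voxels is under-resolved (~3 voxels across), so
throat *area* is underestimated — localization of the minimum and the
inverse-area/velocity coupling remain accurate, which is what the
acceptance checks assert; throat-area accuracy additionally requires ≥ 6
voxels across the throat.

## Pipeline orchestration

`run_pipeline` executes phantom → preprocess → PCMRA → segment → metrics →
flowquant, each stage writing plain files (HDF5/NIfTI/CSV/JSON) so stages
can be re-run independently. The manifest records each stage's parameter
block verbatim, every output file with its SHA-256 hash, and wall time;
identical config + seed reproduces all artifact hashes bit-identically
(HDF5 writes are timestamp-free, NIfTI gzip streams are deterministic).
When no trained model is supplied, the segment stage passes the phantom
truth mask through as the reference segmentation and says so in the
manifest; supplying `model_path` switches to network inference, and a
missing model fails pre-flight before any computation.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
phantoms: tubes of ~40 mm at 0.4 mm voxels (24×24×110 grids), a
bifurcation at 60×80×80, training sets of 8 volumes at 64×64×32 with a
~3.6k-parameter network for 40 epochs. These sizes keep every experiment
at the scale of minutes on a single CPU while staying above 8 voxels per
vessel diameter, the resolution at which the discretization bounds quoted
above hold.
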