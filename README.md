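# cereflow

Automated analysis of intracranial dual-VENC 4D flow MRI: phase-contrast MR
angiography (PCMRA), dense-block 3D U-Net vessel segmentation, and
centerline-based hemodynamic quantification — validated end to end on
synthetic flow phantoms with analytic ground truth.

## Who this is for

4D flow MRI encodes time-resolved, three-directional blood velocity over a
3D volume, giving simultaneous access to morphology (lumen geometry) and
hemodynamics (velocities, flow rates) of the cerebral arteries and sinuses.
Turning a raw acquisition into per-vessel numbers requires a chain of
steps — velocity preprocessing, angiogram computation, vessel segmentation,
centerline extraction, cross-sectional measurement — that is usually
assembled from manual tools. `cereflow` implements this chain as a single
reproducible pipeline for researchers working with intracranial 4D flow
data or developing segmentation methods for it.

Because clinical intracranial 4D flow datasets are generally not shareable,
the package also contains a first-class phantom generator: tubular vessels
(straight, curved, stenosed, bifurcating) carrying Poiseuille flow with
cardiac-cycle modulation, rendered to magnitude + velocity volumes with
controllable noise and velocity aliasing, each paired with its exact
analytic truth (mask, centerline, area profile, flow rate). Every
quantitative claim in the test suite is checked against these closed forms.

## The methods at the core

**PCMRA (pseudo-complex difference).** Per voxel, over N cardiac phases
with speed `v_i = sqrt(vx² + vy² + vz²)` and magnitude `I_i`:

```
PCMRA = (1/N) Σ_i  { I_i · sin(π v_i / VENC) · v_i    if v_i < (2/3) VENC
                    { I_i                              otherwise
```

Static tissue (v = 0) is suppressed to exactly zero; fast voxels keep their
mean magnitude. A smooth normalized variant `I_i · sin(π v_i / (2 VENC))`
is available behind a flag.

**Preprocessing.** Quantile noise masking on the time-averaged magnitude;
eddy-current correction by least-squares fitting a low-order spatial
polynomial to the temporal-mean velocity of static tissue and subtracting
it; dual-VENC anti-aliasing, replacing each low-VENC value by the replica
`v_low + 2·VENC_low·k` nearest the high-VENC measurement.

**Segmentation.** A symmetric 3D U-Net whose convolution stages are dense
blocks (each unit: BN → ReLU → 3×3×3 conv → dropout, fed the concatenation
of all prior feature maps of the block), max-pooling down, transposed
convolutions up with skip concatenation, 1×1×1 conv + softmax head, trained
with a composite softmax-cross-entropy + Dice loss (batch size 1, no
patching, no augmentation). The network is implemented directly in numpy
(im2col GEMM convolutions with analytic gradients, Adam), sized for
desk-scale experiments, and bit-reproducible under a fixed seed.

**Flow quantification.** Vessel centerlines via penalized-geodesic paths on
the voxel graph (weighted by inverse squared distance-to-boundary, so paths
hug the axis), perpendicular analysis planes every 0.25 mm, exclusion of
planes near junctions and vessel ends, cross-sectional lumen area / peak
velocity / flow rate per plane (4× oversampled trilinear sampling; flows in
ml/s from `Σ v·n dA`), per-vessel medians, and the flow conservation error

```
fce = | 1 − (Σ outflows) / (Σ inflows) |
```

**Agreement & statistics.** Dice score, symmetric Hausdorff distance and
average symmetric surface distance on boundary voxels (mm); relative
Bland-Altman bias and limits of agreement; ICC(2,1); and a Shapiro-Wilk
gate choosing between an unpaired t-test and a Mann-Whitney U.

## Worked example

```python
import numpy as np
from cereflow import TubeSpec, make_tube_phantom
from cereflow.flow import quantify_vessels

# noiseless Poiseuille tube: R = 2 mm, v_max = 0.5 m/s, 0.4 mm voxels
shape, spacing = (24, 24, 110), (0.4, 0.4, 0.4)
c = (np.array(shape) - 1) / 2 * 0.4
spec = TubeSpec(start=[c[0], c[1], 2.4], end=[c[0], c[1], 41.0],
                radius_mm=2.0, v_max=0.5, label="tube")
vol, truth = make_tube_phantom(spec, shape, spacing)

summaries, _ = quantify_vessels(vol, truth.mask)
s = summaries[0]
print(f"area  {s.median_area_mm2:.2f} mm^2   (pi R^2      = {np.pi*4:.2f})")
print(f"flow  {s.median_mean_flow_mls:.2f} ml/s   (v_max pi R^2/2 = {np.pi:.2f})")
print(f"peak  {s.median_peak_velocity_ms:.2f} m/s    (v_max       = 0.50)")
```

prints

```
area  12.75 mm^2   (pi R^2      = 12.57)
flow  3.10 ml/s   (v_max pi R^2/2 = 3.14)
peak  0.49 m/s    (v_max       = 0.50)
```

i.e. the measured median lumen area is within 1.5% of the analytic πR²,
the median flow within 1.3% of the Poiseuille value v_max·πR²/2, and the
peak velocity within 2% of the prescribed maximum — all discretization
error, since the phantom is noiseless.

The same pipeline runs from the shell:

```
cereflow phantom --preset bifurcation --dims 48,64,64 --seed 1 --out run/
cereflow run --preset bifurcation --seed 1 --out run/
cereflow flowquant --flow run/flow.h5 --mask run/truth_mask.nii.gz --fce --out report.csv
```

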