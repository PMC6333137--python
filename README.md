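# tiltmar

Metal implants (hip prostheses, dental fillings) corrupt CT images with
streaks and dark bands — photon starvation, beam hardening and noise along
rays that traverse the metal. For radiotherapy planning this corruption
directly degrades target delineation and dose calculation. `tiltmar`
implements a metal-artifact-reduction (MAR) approach that acquires a **second
CT scan at a tilted gantry angle**: the tilted scan's artifacts land in
different places, so the two reconstructions carry complementary clean
regions that can be fused into a nearly artifact-free image.

The package bundles everything needed to study the method quantitatively:

* a polychromatic equiangular **fan-beam CT simulator** (120 kVp six-bin
  spectrum, Beer-Lambert per energy bin, Poisson counting noise, Gaussian
  log-domain noise, photon-starvation clamping) and filtered backprojection;
* parametric pelvis-like and head-like **voxel phantoms** with embedded metal
  rods, oblique slicing, and soft-tissue texture;
* the core **T-MAR fusion** and its augmented second pass (**AT-MAR**);
* the classical sinogram-inpainting baselines **LI-MAR** and **NMAR**;
* ROI-based evaluation (mean absolute percentage error, MAPE).

## Method

Let `I_ori` and `I_tilt` be co-registered reconstructions of the ordinary and
tilted scans. Their difference

```
I_artifact = I_ori − I_tilt
```

cancels the (shared) anatomy and superposes both scans' metal artifacts. Each
denoised image is then correlated patchwise (5×5) against this map with a
**modified structural similarity index** that keeps only the contrast and
structure factors,

```
SSIM′(x, y) = c(x, y) · s(x, y)
c = (2 σx σy + c2) / (σx² + σy² + c2)
s = (σxy + c3) / (σx σy + c3)
```

(the luminance factor is dropped: image and artifact-map intensities differ
grossly even where their structure matches, so full SSIM mis-ranks the
contaminated regions). With

```
C_ori = SSIM′(I_ori, I_artifact)      C_tilt = SSIM′(I_tilt, −I_artifact)
```

a high correlation marks local contamination, and the fused image takes the
less-contaminated source per pixel:

```
I_G = I_ori  where C_ori < C_tilt,  else I_tilt.
```

When the tilt cannot fully separate the implants, both scans keep residual
artifacts; **AT-MAR** runs the same workflow a second time between the T-MAR
result and a sinogram-inpainting MAR image (NMAR) of the ordinary scan.

## Worked example

```python
from tiltmar.study import pelvis_study

res = pelvis_study(seed=0, n_realizations=10)
for method, med in sorted(res.medians().items(), key=lambda kv: kv[1]):
    print(f"{method:10s} {med:6.2f} % MAPE")
```

prints (median soft-tissue-ROI MAPE over ten noise realizations of the
pelvis simulation with bilateral steel implants, 0°/10° scans):

```
tmar         9.69 % MAPE
tilted       9.77 % MAPE
nmar         9.88 % MAPE
limar       10.11 % MAPE
original    15.60 % MAPE
```

The ordinary scan is the worst (severe dark band between the implants); the
tilted scan alone removes most of that; the inpainting baselines trail the
tilted scan; and the fused T-MAR image is best. The head study adds the
augmented pass for the insufficient-tilt case:

```python
from tiltmar.study import head_study
m = head_study(seed=0, n_realizations=3).medians()
print(m["tmar"], m["atmar"])   # 18.52 14.72  — the second pass helps
```

A CLI mirrors the library (`tiltmar run`, `tiltmar mar`, `tiltmar baseline`,
`tiltmar evaluate`); see `tiltmar --help`.

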