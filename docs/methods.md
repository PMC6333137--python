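# Methods

This note documents the models, parameter choices and known limitations of
`tiltmar`: what exactly is simulated, which decisions were genuinely open,
and what the simulation studies do and do not demonstrate about real data.

## Scan and physics model

The simulator is a 2-D third-generation fan-beam CT: a point source on a
circle of radius SID around the isocenter, an equiangular detector arc at
SDD, 720 views over 360°. Defaults mirror the two study geometries
(pelvis: SID 400 mm / SDD 1100 mm; head: SID 605 mm / SDD 1062 mm). The
detector has 729 channels by default; channel pitch is sized so the arc
covers the field of view with a 2 % margin (these detector parameters are
modelling choices; only SID/SDD/views are study constraints).

A polychromatic beam is modelled as discrete energy bins. At 120 kVp with six
bins the centers are 20, 40, …, 120 keV. Bin weights integrate a
filtered-Kramers tungsten continuum — bremsstrahlung ∝ (E_max−E)/E times
2.5 mm Al inherent filtration — over each bin; characteristic lines are
omitted. The weights are therefore deterministic, and the single-bin
degenerate case collapses to the continuum's mean energy.

Per detector bin the noise-free measurement is

    counts = i0 · Σ_i w_i · exp(−L_i),

with L_i the monochromatic line integral at bin energy E_i. Beam hardening
(cupping, dark bands) and photon starvation behind metal both *emerge* from
this sum; they are not injected separately. Noise: Poisson on the counts
(i0 = 1e7 incident photons per channel by default) and zero-mean Gaussian of
variance 0.001 on the log-transformed data, from two independent RNG streams
spawned from one user seed. Zero counts clamp to one count before the log.
Scatter, detector cross-talk, bowtie filtration and helical geometry are out
of scope.

Attenuation coefficients are bundled as a CSV (NIST-XCOM-derived values,
rounded, times nominal densities) with log-log interpolation in energy.
Cerrobend keeps its K-edge structure near 88–91 keV; monotone decrease is
only guaranteed (and asserted) for water/tissue/bone over 20–120 keV.

## Projection and reconstruction

Forward projection is ray-driven with bilinear sampling at a step of half a
pixel (configurable); an exact adjoint (bilinear splat) is provided for
consistency testing. Reconstruction is standard equiangular fan-beam FBP:
cosine weighting, convolution with the discrete equiangular ramp kernel,
inverse-square-distance backprojection. The library default apodizes the
ramp with a Hann window (robust general-purpose choice); the *studies*
reconstruct with the pure ramp, the classical fan-beam default, which keeps
artifact structure sharp — the patch-based correlation can only recognise
artifacts that retain local structure, and heavier smoothing both blurs
them and biases the selection statistics.

## Phantoms

Real study objects (an anthropomorphic numerical pelvis, a physical head
phantom) are emulated by parametric voxel phantoms:

* **Pelvis** (256², 0.15 cm pixels, ~33×19 cm body): soft-tissue ellipse,
  subcutaneous fat layer, visceral fat pockets, a fluid-filled bladder,
  bowel/rectal gas pockets, a sacrum, and two femoral bone cylinders each
  carrying an embedded 0.85 cm-radius steel rod (hip-implant analogue; the
  implant material is a choice — titanium is too transparent above 100 keV
  to produce the photon starvation that drives the severe 0° artifacts).
* **Head** (256², 0.1 cm pixels): tissue ellipse, gypsum skull ring and
  gingiva block, two 0.6 cm cerrobend rods.

Soft-tissue classes are modulated by a seeded, axially columnar, correlated
texture field (pelvis: 5 % relative amplitude, 0.8 cm correlation length).
This matters for the baselines: sinogram inpainting cannot recover structure
it never measured, and without heterogeneity the class-prior methods are
unrealistically accurate. Phantom generation is deterministic given its
config (the texture seed is part of the config).

**Tilt geometry.** A tilt about the lateral axis moves the cutting plane in
z proportionally to the AP coordinate, so two bilateral rods can only be
separated if they differ in AP position and z-extent. The default pelvis
offsets the rods ±2 cm AP and staggers their z-extents so the 0° slice
contains both rods while any plane tilted ≥10° misses one — the geometric
premise of the method (rays through *both* implants cause the worst
artifacts). The default head separates analogously at 15° about the other
axis; the studies instead use full-length rods (`with_long_rods`) so *both*
cross-sections stay in the tilted slice: the deliberately insufficient-tilt
case that motivates the augmented pass.

Oblique slices are nearest-neighbor label lookups (labels are categorical).
Two parametrizations exist: the default preserves in-plane spacing (a sphere
cuts to a circle of its true radius); `registered=True` samples above the
axial grid — the ideal oblique-to-axial reformat — and is what the studies
scan for the tilted acquisition, so the image pair is pixelwise co-registered
without a resampling step (resampling would asymmetrically smooth one image's
noise). For measured data, `align_tilted` applies the cos-foreshortening
reformat explicitly.

## The fusion

Defaults: 5×5 uniform patch window with reflective borders; exponents 1;
stabilizers c2 = (0.03 R)², c3 = c2/2 where R is a robust (0.5–99.5
percentile) dynamic range of the two inputs' union — metal pixels would
otherwise inflate the stabilizers until both factors saturate at 1
everywhere. (Empirically the per-pixel *comparison* of the two maps is very
insensitive to the stabilizer scale; the robust range mainly keeps the maps
themselves interpretable.)

The denoising sigma ahead of the correlation is 0.5 px. This was calibrated
on the pelvis study: at the study's noise level the raw noise correlation
between an image and the difference map is itself a useful signal (the
noisier scan correlates more strongly with the map), and heavy smoothing
destroys it while leaving near-tie coin flips; light smoothing gave the best
and most stable fusion. The fused image samples the **raw** reconstructions
(selection maps come from the denoised ones): fusing denoised pixels wins
error metrics by smoothing alone, which is inconsistent with the modest
fusion gains the approach actually delivers, so it is off by default
(`fuse_denoised` switches it).

Metal pixels (above 1.2 cm⁻¹, ≈ twice cortical bone) are excluded from the
selection rule and copied from the ordinary scan — the per-pixel rule
concerns artifact regions, not the implants. A cheap misuse guard requires
the high-attenuation masks of the two inputs to overlap (NCC ≥ 0.7); no
registration is performed.

AT-MAR's augmenting image defaults to NMAR of the ordinary scan's virtual
sinogram; any externally produced MAR image can be passed instead.

## Baselines

LI-MAR: per-view 1-D linear interpolation across the metal-trace intervals
of the (virtual) sinogram, FBP, metal re-insertion. NMAR: the sinogram is
normalized by the forward projection of a class prior (air → 0, soft tissue
→ class median, bone kept, metal → tissue), interpolated in the normalized
domain, denormalized, reconstructed, metal re-inserted. The prior is
classified on a 1 px-smoothed image (thresholding raw noise spikes scatters
misclassified pixels); thresholds default to 0.10 and 0.35 cm⁻¹ (≈ −500 and
+700 HU). The metal trace is dilated by two bins: trace-edge bins carry
blooming/partial-volume corruption.

## Evaluation

MAPE is computed against an artifact-free reference: the *same*
noise-free polychromatic simulation with the metal replaced by its
surrounding material (bone for the femur-embedded pelvis implants, gypsum
for the head). Using identical beam physics makes body-driven cupping common
mode, so the metric isolates metal-specific corruption. The pelvis study
evaluates eight rectangular soft-tissue boxes — three along the
inter-implant corridor where the 0° artifacts concentrate, five in general
soft tissue — each intersected with the eroded tissue mask minus a 3-px
dilated metal neighbourhood. Whole-organ masks were rejected: they dilute
the localized artifact differences below the noise floor and the method
comparison degenerates.

## Study sizes and determinism

Both studies run at 256² with 720 views; the pelvis study uses ten noise
realizations, the head study three (noise-free projections are shared across
realizations; only the noise draws differ). A full pelvis study takes
roughly two minutes on one CPU. All randomness descends from a single seed
via spawned `SeedSequence` streams; identical seeds give identical results.

## Known limitations

* The pelvis fusion's margin over the tilted scan alone is small and
  noise-sensitive. This is structural: when the tilt fully separates the
  implants, the tilted slice contains a strict subset of the metal, so the
  ordinary scan is almost nowhere systematically better and the fusion's
  optimum is close to "tilted everywhere". Real gains concentrate in
  realizations where the tilted scan draws bad starvation noise. The
  insufficient-tilt head study is the regime where fusion genuinely matters,
  and there the augmented pass gives a large improvement.
* Fusion boundaries are not smoothed; per-pixel switching can leave visible
  seams (a known property of the selection rule).
* 2-D slices cannot show out-of-plane (cone/partial-volume) effects of a
  real tilted acquisition, and the phantoms' texture is axially columnar, so
  the tilted slice sees exactly the axial anatomy; real anatomy varies along
  z and would add reformat error to the tilted scan.
* Absolute MAPE values depend on phantom realism and ROI placement and are
  not comparable across studies; only the relative method ordering is
  meaningful here.
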