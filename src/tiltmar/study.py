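"""Replication studies: simulate, reconstruct, run all MAR methods, evaluate.

Two study setups mirror the two experimental conditions:

* ``pelvis_study`` - pelvis-like phantom with bilateral 0.85 cm steel rods,
  scans at 0 and 10 degrees (the tilt fully separates the implants), SID
  400 mm / SDD 1100 mm, 720 views, 120 kVp six-bin spectrum, Poisson noise at
  i0 = 1e7 and Gaussian log-domain noise of variance 0.001.  Methods
  evaluated: original, tilted, LI-MAR, NMAR, T-MAR.
* ``head_study`` - head-like phantom with two 0.6 cm cerrobend rods and a
  deliberately insufficient 15-degree tilt (both scans keep residual
  artifacts), SID 605 mm / SDD 1062 mm.  Adds AT-MAR.

Noise-free polychromatic counts are computed once per scan and shared across
noise realizations; only the Poisson/Gaussian draws differ per realization.
The artifact-free reference is the FBP of the noise-free polychromatic
sinogram of the same slice with the metal replaced by the surrounding
material, so body-driven beam hardening is common mode and cancels in the
error metric; metal pixels are excluded from the ROI regardless.  The studies
reconstruct with the pure ramp filter (the classical fan-beam default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .baselines import (TraceMask, build_prior, limar, metal_trace, nmar,
                        segment_metal)
from .evaluate import ROISet, mape, soft_tissue_roi
from .phantoms import (HeadConfig, MaterialSlice, PelvisConfig,
                       make_head_phantom, make_pelvis_phantom, oblique_slice)
from .physics import Spectrum, make_spectrum
from .projection import (FanBeamGeometry, IntensitySinogram, Sinogram,
                         add_gaussian, add_poisson, log_transform,
                         simulate_polychromatic, virtual_sinogram)
from .recon import ReconImage, fbp
from .tmar import PipelineParams, atmar_pipeline, tmar_pipeline

__all__ = [
    "NoiseModel",
    "pelvis_geometry",
    "head_geometry",
    "simulate_counts",
    "realize_scan",
    "align_tilted",
    "reference_image",
    "StudyResult",
    "evaluation_rois",
    "PELVIS_ROI_BOXES",
    "pelvis_study",
    "head_study",
]


@dataclass(frozen=True)
class NoiseModel:
    i0: float = 1e7
    gaussian_variance: float = 0.001
    poisson: bool = True


def pelvis_geometry(n_views: int = 720, n_channels: int = 729) -> FanBeamGeometry:
    return FanBeamGeometry(sid_mm=400.0, sdd_mm=1100.0, n_views=n_views,
                           n_channels=n_channels, fov_radius_mm=175.0)


def head_geometry(n_views: int = 720, n_channels: int = 729) -> FanBeamGeometry:
    return FanBeamGeometry(sid_mm=605.0, sdd_mm=1062.0, n_views=n_views,
                           n_channels=n_channels, fov_radius_mm=110.0)


def simulate_counts(sl: MaterialSlice, sp: Spectrum, geom: FanBeamGeometry,
                    noise: NoiseModel) -> IntensitySinogram:
    """Noise-free polychromatic counts for one scan (shared by realizations)."""
    return simulate_polychromatic(sl, sp, geom, i0=noise.i0)


def realize_scan(counts: IntensitySinogram, noise: NoiseModel,
                 rng_poisson: np.random.Generator,
                 rng_gauss: np.random.Generator,
                 n: int, pixel_size: float, tilt_deg: float = 0.0,
                 apodization: str = "hann") -> ReconImage:
    """One noisy acquisition + reconstruction from precomputed clean counts."""
    noisy = add_poisson(counts, rng_poisson) if noise.poisson else counts
    sino = log_transform(noisy)
    sino = add_gaussian(sino, noise.gaussian_variance, rng_gauss)
    img = fbp(sino, n=n, pixel_size=pixel_size, apodization=apodization)
    return dc_replace(img, tilt_deg=tilt_deg)


def align_tilted(img: ReconImage, tilt_deg: float, axis: str = "x") -> ReconImage:
    """Reformat a tilted-scan reconstruction onto the axial anatomy grid.

    A pixel at in-plane coordinate v of a plane tilted by theta sits at
    anatomical coordinate ``v * cos(theta)`` along the tilt direction, so the
    tilted image is foreshortening-stretched relative to the axial scan of the
    same anatomy.  The MAR fusion requires co-registered inputs; this applies
    the (known, rigid) cos-scaling about the image center - the simulation
    counterpart of the clinical oblique-to-axial reformat.  ``axis`` is the
    rotation axis: "x" scales rows (AP direction), "y" scales columns.
    """
    from scipy.ndimage import affine_transform

    th = np.deg2rad(tilt_deg)
    c = np.cos(th)
    if abs(c - 1.0) < 1e-12:
        return img
    n, m = img.shape
    ci, cj = (n - 1) / 2, (m - 1) / 2
    if axis == "x":
        mat = np.array([[1.0 / c, 0.0], [0.0, 1.0]])
        off = np.array([ci - ci / c, 0.0])
    else:
        mat = np.array([[1.0, 0.0], [0.0, 1.0 / c]])
        off = np.array([0.0, cj - cj / c])
    vals = affine_transform(img.values, mat, offset=off, order=1, mode="nearest")
    return dc_replace(img, values=vals)


def reference_image(sl: MaterialSlice, sp: Spectrum, geom: FanBeamGeometry,
                    n: int, pixel_size: float,
                    metal_replacement: str = "soft_tissue",
                    apodization: str = "hann") -> ReconImage:
    """Artifact-free reference: the same polychromatic noise-free simulation
    with the metal replaced by the surrounding material.

    Using identical beam physics for the reference means body-driven beam
    hardening (cupping) is common to the reference and every evaluated image
    and cancels in the error metric, isolating the metal-specific corruption.
    """
    labels = sl.labels.copy()
    metal_ids = [i for i, m in enumerate(sl.materials)
                 if m in ("steel", "titanium", "cerrobend")]
    repl = sl.materials.index(metal_replacement)
    for mid in metal_ids:
        labels[labels == mid] = repl
    clean = MaterialSlice(labels, sl.spacing, sl.materials, sl.tilt_deg,
                          texture=sl.texture)
    counts = simulate_polychromatic(clean, sp, geom, i0=1.0)
    sino = Sinogram(-np.log(np.maximum(counts.counts, 1e-30)), geom)
    return fbp(sino, n=n, pixel_size=pixel_size, apodization=apodization)


@dataclass(frozen=True)
class StudyResult:
    """Per-method MAPE across noise realizations, plus last-realization images."""

    mapes: dict[str, list[float]]
    images: dict[str, ReconImage]
    reference: ReconImage
    roi: ROISet
    seed: int

    def median(self, method: str) -> float:
        return float(np.median(self.mapes[method]))

    def medians(self) -> dict[str, float]:
        return {m: self.median(m) for m in self.mapes}


def evaluation_rois(sl: MaterialSlice,
                    boxes: dict[str, tuple[float, float, float, float]]) -> ROISet:
    """Rectangular soft-tissue evaluation boxes (cm), intersected with the
    eroded tissue mask so bone, metal neighbourhoods and gas are excluded."""
    base = soft_tissue_roi(sl).union()
    n = sl.labels.shape[0]
    c = (n - 1) / 2
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    x = (jj - c) * sl.spacing
    y = (c - ii) * sl.spacing
    masks = {}
    for name, (cx, cy, w, h) in boxes.items():
        m = (np.abs(x - cx) <= w / 2) & (np.abs(y - cy) <= h / 2) & base
        if m.any():
            masks[name] = m
    return ROISet(masks)


# evaluation regions of the pelvis replication: three boxes along the
# inter-implant corridor where the 0-degree artifacts concentrate, plus
# anterior/posterior/lateral soft-tissue boxes away from the implants
PELVIS_ROI_BOXES = {
    "band_left": (-4.0, -1.0, 4.0, 2.4),
    "band_center": (0.0, 0.0, 3.0, 2.2),
    "band_right": (4.0, 1.0, 4.0, 2.4),
    "anterior": (0.0, 4.8, 7.0, 2.2),
    "posterior_left": (-6.0, -5.0, 4.0, 3.0),
    "posterior_right": (6.0, -5.0, 4.0, 3.0),
    "lateral_left": (-12.5, 0.0, 3.0, 3.0),
    "lateral_right": (12.5, 0.0, 3.0, 3.0),
}

_PRIOR_SMOOTH_SIGMA = 1.0  # px, image denoising before prior classification


def _study(sl0: MaterialSlice, sl_t: MaterialSlice, geom: FanBeamGeometry,
           sp: Spectrum, noise: NoiseModel, seed: int, n_realizations: int,
           metal_replacement: str, with_atmar: bool,
           mar_params: PipelineParams | None = None,
           tilt_axis: str = "x", apodization: str = "hann",
           roi: ROISet | None = None) -> StudyResult:
    n = sl0.labels.shape[0]
    px = sl0.spacing
    counts0 = simulate_counts(sl0, sp, geom, noise)
    counts_t = simulate_counts(sl_t, sp, geom, noise)
    ref = reference_image(sl0, sp, geom, n, px, metal_replacement, apodization)
    roi = roi or soft_tissue_roi(sl0)
    params = mar_params or PipelineParams()

    mapes: dict[str, list[float]] = {}
    images: dict[str, ReconImage] = {}
    root = np.random.SeedSequence(seed)
    for r_ss in root.spawn(n_realizations):
        sp_p, sp_g = r_ss.spawn(2)
        rng_p = np.random.default_rng(sp_p)
        rng_g = np.random.default_rng(sp_g)
        ori = realize_scan(counts0, noise, rng_p, rng_g, n, px, 0.0,
                           apodization)
        tilt = realize_scan(counts_t, noise, rng_p, rng_g, n, px,
                            sl_t.tilt_deg, apodization)

        metal = segment_metal(ori, params.metal_threshold or 1.2)
        trace = metal_trace(metal, geom, px)
        if trace.values.any():
            from scipy.ndimage import binary_dilation

            # transition bins at the trace edge carry blooming/partial-volume
            # corruption; dilating the trace is standard practice
            trace = TraceMask(binary_dilation(trace.values, iterations=2))
        vsino = virtual_sinogram(ori, geom)
        li = limar(vsino, trace, metal=metal, uncorrected=ori, n=n,
                   pixel_size=px, apodization=apodization)
        # NMAR prior: classify a lightly denoised image (thresholding the raw
        # noisy reconstruction mislabels noise spikes)
        from scipy.ndimage import gaussian_filter

        smoothed = dc_replace(ori, values=gaussian_filter(
            ori.values, _PRIOR_SMOOTH_SIGMA))
        prior = build_prior(smoothed, metal)
        nm = nmar(vsino, trace, prior, metal=metal, uncorrected=ori,
                  n=n, pixel_size=px, apodization=apodization)
        tm = tmar_pipeline(ori, tilt, params)

        images = {"original": ori, "tilted": tilt, "limar": li, "nmar": nm,
                  "tmar": tm.fused}
        if with_atmar:
            at = atmar_pipeline(ori, tilt, params, augment=nm)
            images["atmar"] = at.fused
        for name, img in images.items():
            mapes.setdefault(name, []).append(mape(img, ref, roi))
    return StudyResult(mapes, images, ref, roi, seed)


def pelvis_study(seed: int = 0, n_realizations: int = 10,
                 cfg: PelvisConfig | None = None,
                 geom: FanBeamGeometry | None = None,
                 tilt_deg: float = 10.0,
                 noise: NoiseModel = NoiseModel(),
                 mar_params: PipelineParams | None = None,
                 apodization: str = "ramp") -> StudyResult:
    """Pelvis replication: bilateral rods separated by a 10-degree tilt."""
    ph = make_pelvis_phantom(cfg)
    sl0 = oblique_slice(ph, 0.0)
    # registered=True: the ideal oblique-to-axial reformat, so the pair meets
    # the fusion's co-registration precondition without a resampling step
    sl_t = oblique_slice(ph, tilt_deg, registered=True)
    geom = geom or pelvis_geometry()
    sp = make_spectrum(120.0, 6)
    roi = evaluation_rois(sl0, PELVIS_ROI_BOXES)
    return _study(sl0, sl_t, geom, sp, noise, seed, n_realizations,
                  "bone", with_atmar=False, mar_params=mar_params,
                  apodization=apodization, roi=roi)


def head_study(seed: int = 0, n_realizations: int = 3,
               cfg: HeadConfig | None = None,
               geom: FanBeamGeometry | None = None,
               tilt_deg: float = 15.0,
               insufficient_tilt: bool = True,
               noise: NoiseModel = NoiseModel(),
               mar_params: PipelineParams | None = None,
               apodization: str = "ramp") -> StudyResult:
    """Head replication with (by default) insufficient tilt: both scans keep
    residual artifacts, so the augmented second pass (AT-MAR) is needed."""
    cfg = cfg or HeadConfig()
    if insufficient_tilt:
        cfg = cfg.with_long_rods()
    ph = make_head_phantom(cfg)
    sl0 = oblique_slice(ph, 0.0)
    sl_t = oblique_slice(ph, tilt_deg, registered=True)
    geom = geom or head_geometry()
    sp = make_spectrum(120.0, 6)
    return _study(sl0, sl_t, geom, sp, noise, seed, n_realizations,
                  "gypsum", with_atmar=True, mar_params=mar_params,
                  tilt_axis="y", apodization=apodization)
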