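"""Tilted-scan metal artifact reduction (T-MAR) and its augmented pass (AT-MAR).

The method fuses an ordinary (0-deg) and a gantry-tilted reconstruction of the
same anatomy.  Because streak and band artifacts depend on the beam direction
through the implants, the two scans are corrupted in different places while
the anatomy is (nearly) identical; their pixelwise difference

    I_artifact = I_ori - I_tilt

is therefore a superposition map of both scans' artifacts carrying no
anatomy.  A modified structural-similarity index - contrast and structure
factors only, the luminance factor deliberately excluded -

    SSIM'(x, y) = c(x, y)^beta * s(x, y)^gamma
    c = (2 sx sy + c2) / (sx^2 + sy^2 + c2)
    s = (sxy + c3) / (sx sy + c3)

is evaluated over sliding patches (5x5 by default) between each denoised
reconstruction and the superposition map:

    C_ori  = SSIM'(I_ori,  I_artifact)
    C_tilt = SSIM'(I_tilt, -I_artifact)

(the sign flip keeps the tilted scan's own artifacts positively correlated).
A high correlation means the image locally resembles the artifact map, i.e.
is contaminated, so the fused image takes, per pixel, the source with the
*lower* correlation:

    I_G = I_ori  where C_ori < C_tilt,  else I_tilt.

When the tilt cannot fully separate the implants (both scans keep residual
artifacts), a second pass fuses the first result with a sinogram-inpainting
MAR image (NMAR here) - the augmented variant, AT-MAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from .recon import ReconImage

__all__ = [
    "SSIMParams",
    "PipelineParams",
    "ArtifactMap",
    "CorrelationMap",
    "MARResult",
    "denoise",
    "artifact_split",
    "modified_ssim_map",
    "correlation_maps",
    "fuse",
    "tmar_pipeline",
    "atmar_pipeline",
]


@dataclass(frozen=True)
class SSIMParams:
    """Patch size, stabilizers and exponents of the modified SSIM.

    ``c2 = (0.03 R)^2`` and ``c3 = c2 / 2`` with R a robust (0.5-99.5
    percentile) dynamic range of the two inputs' union unless given
    explicitly - metal pixels would otherwise inflate the stabilizers until
    the factors saturate.  ``include_luminance`` restores
    the full SSIM (luminance stabilizer ``c1 = (0.01 R)^2``) and exists only
    to demonstrate why the luminance factor must be dropped.
    """

    patch: int = 5
    c2: float | None = None
    c3: float | None = None
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    dynamic_range: float | None = None
    include_luminance: bool = False

    def __post_init__(self):
        if self.patch < 3 or self.patch % 2 == 0:
            raise ValueError("patch must be odd and >= 3")
        for name in ("c2", "c3", "dynamic_range"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PipelineParams:
    """Tunables of the full T-MAR pipeline."""

    sigma: float = 0.5  # denoising Gaussian sigma, pixels (see methods note)
    ssim: SSIMParams = field(default_factory=SSIMParams)
    fuse_denoised: bool = False  # fuse raw reconstructions by default
    metal_threshold: float | None = 1.2  # 1/cm; None disables metal handling
    registration_check: bool = True
    registration_threshold: float = 0.7  # min NCC of high-attenuation masks
    bone_threshold: float = 0.35  # 1/cm, for the registration guard


@dataclass(frozen=True)
class ArtifactMap:
    """Superposition of both scans' metal artifacts: I_ori - I_tilt."""

    values: np.ndarray
    provenance: tuple[str, str] = ("ordinary", "tilted")


@dataclass(frozen=True)
class CorrelationMap:
    """Per-pixel modified-SSIM correlation against the artifact map."""

    values: np.ndarray
    patch: int

    def __post_init__(self):
        if np.max(np.abs(self.values), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("correlation values must lie in [-1, 1]")


@dataclass(frozen=True)
class MARResult:
    """Fused image plus all intermediates of a T-MAR (or AT-MAR) run."""

    fused: ReconImage
    mask: np.ndarray  # True where the ordinary scan was selected
    c_ori: CorrelationMap
    c_tilt: CorrelationMap
    artifact: ArtifactMap
    params: PipelineParams
    metal_mask: np.ndarray | None = None
    stage1: "MARResult | None" = None  # first pass of AT-MAR
    augment: ReconImage | None = None  # the inpainting-MAR image of AT-MAR


def denoise(img: ReconImage, sigma: float) -> ReconImage:
    """Gaussian smoothing with reflective boundaries; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img
    return replace(img, values=gaussian_filter(img.values, sigma, mode="reflect"))


def _check_pair(a: ReconImage, b: ReconImage):
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.units != b.units:
        raise ValueError(f"image units differ: {a.units} vs {b.units}")


def artifact_split(ori: ReconImage, tilt: ReconImage) -> ArtifactMap:
    """Difference image containing both scans' artifacts but no anatomy."""
    _check_pair(ori, tilt)
    return ArtifactMap(ori.values - tilt.values)


def _as_array(img) -> np.ndarray:
    return img.values if hasattr(img, "values") else np.asarray(img, dtype=float)


def modified_ssim_map(x, y, p: SSIMParams | None = None) -> CorrelationMap:
    """Sliding-window modified SSIM between two images.

    Local means/variances/covariance use a uniform ``patch x patch`` window
    with reflective boundaries; the map has the input shape.  With default
    exponents the value is the product of the contrast and structure factors
    (plus the luminance factor if ``include_luminance``).
    """
    p = p or SSIMParams()
    xa, ya = _as_array(x), _as_array(y)
    if xa.shape != ya.shape:
        raise ValueError("images must share a shape")
    if p.patch > min(xa.shape):
        raise ValueError("patch larger than image")

    R = p.dynamic_range
    if R is None:
        R = _robust_range(xa, ya)
    c2 = p.c2 if p.c2 is not None else (0.03 * R) ** 2
    c3 = p.c3 if p.c3 is not None else c2 / 2.0

    win = dict(size=p.patch, mode="reflect")
    mx = uniform_filter(xa, **win)
    my = uniform_filter(ya, **win)
    vx = np.maximum(uniform_filter(xa * xa, **win) - mx * mx, 0.0)
    vy = np.maximum(uniform_filter(ya * ya, **win) - my * my, 0.0)
    cov = uniform_filter(xa * ya, **win) - mx * my
    sx = np.sqrt(vx)
    sy = np.sqrt(vy)

    c = (2.0 * sx * sy + c2) / (vx + vy + c2)
    s = (cov + c3) / (sx * sy + c3)
    vals = _signed_pow(c, p.beta) * _signed_pow(s, p.gamma)
    if p.include_luminance:
        c1 = (0.01 * R) ** 2
        lum = (2.0 * mx * my + c1) / (mx * mx + my * my + c1)
        vals = _signed_pow(lum, p.alpha) * vals
    return CorrelationMap(np.clip(vals, -1.0, 1.0), p.patch)


def _robust_range(*imgs: np.ndarray) -> float:
    """Dynamic range of the images' union, robust to metal outliers.

    Metal pixels reconstruct to attenuation values an order of magnitude above
    any anatomy; a min/max range would inflate the SSIM stabilizers until the
    contrast and structure factors saturate at 1 everywhere.  The 0.5-99.5
    percentile span of the pooled values tracks the anatomical range instead.
    """
    pooled = np.concatenate([i.ravel() for i in imgs])
    lo, hi = np.percentile(pooled, [0.5, 99.5])
    return float(hi - lo) or 1.0


def _signed_pow(a: np.ndarray, e: float) -> np.ndarray:
    if e == 1.0:
        return a
    return np.sign(a) * np.abs(a) ** e


def correlation_maps(ori_d: ReconImage, tilt_d: ReconImage, art: ArtifactMap,
                     p: SSIMParams | None = None,
                     tol: float = 1e-9) -> tuple[CorrelationMap, CorrelationMap]:
    """Correlation of each denoised scan against the artifact-superposition map.

    ``C_ori = SSIM'(ori, art)``; ``C_tilt = SSIM'(tilt, -art)`` - the sign
    flip keeps each scan's own artifacts positively correlated, since the
    superposition map was formed as ordinary-minus-tilted.  Both maps share
    one dynamic range (the two scans' union) so their values are comparable.
    """
    p = p or SSIMParams()
    _check_pair(ori_d, tilt_d)
    if np.max(np.abs(art.values - (ori_d.values - tilt_d.values))) > max(tol, 1e-6):
        raise ValueError("artifact map is not the difference of the given images")
    if p.dynamic_range is None:
        p = replace(p, dynamic_range=_robust_range(ori_d.values, tilt_d.values))
    c_ori = modified_ssim_map(ori_d.values, art.values, p)
    c_tilt = modified_ssim_map(tilt_d.values, -art.values, p)
    return c_ori, c_tilt


def fuse(ori: ReconImage, tilt: ReconImage, c_ori: CorrelationMap,
         c_tilt: CorrelationMap) -> MARResult:
    """Per-pixel selection of the less-contaminated source.

    Takes the ordinary value where ``C_ori < C_tilt`` and the tilted value
    otherwise; ties go to the tilted scan.  Every fused pixel equals one of
    the two inputs exactly.
    """
    _check_pair(ori, tilt)
    if c_ori.values.shape != ori.shape or c_tilt.values.shape != ori.shape:
        raise ValueError("correlation map shape mismatch")
    take_ori = c_ori.values < c_tilt.values
    fused_vals = np.where(take_ori, ori.values, tilt.values)
    fused = replace(ori, values=fused_vals, tilt_deg=0.0)
    art = ArtifactMap(ori.values - tilt.values)
    return MARResult(fused, take_ori, c_ori, c_tilt, art, PipelineParams())


def _registration_guard(ori: ReconImage, tilt: ReconImage, p: PipelineParams):
    """Cheap misuse guard: high-attenuation (bone+metal) masks must overlap."""
    a = ori.values >= p.bone_threshold
    b = tilt.values >= p.bone_threshold
    if not (a.any() and b.any()):
        return  # nothing to compare on (e.g. synthetic fixtures)
    af = a.astype(float) - a.mean()
    bf = b.astype(float) - b.mean()
    denom = np.sqrt((af * af).sum() * (bf * bf).sum())
    if denom == 0:
        return
    ncc = float((af * bf).sum() / denom)
    if ncc < p.registration_threshold:
        raise ValueError(
            f"inputs appear misregistered (mask NCC {ncc:.2f} < "
            f"{p.registration_threshold}); co-registered scans are required"
        )


def tmar_pipeline(ori: ReconImage, tilt: ReconImage,
                  p: PipelineParams | None = None) -> MARResult:
    """Full T-MAR: denoise -> artifact split -> correlation maps -> fusion.

    Correlation maps are computed on the denoised images (the modified SSIM
    is variance-driven and hence noise-sensitive), but the fused output
    samples the raw reconstructions unless ``p.fuse_denoised``.  Metal pixels
    themselves (above ``p.metal_threshold``) are copied from the ordinary
    scan: the selection rule concerns artifact regions, not the implants.
    """
    p = p or PipelineParams()
    _check_pair(ori, tilt)
    if p.registration_check:
        _registration_guard(ori, tilt, p)
    ori_d = denoise(ori, p.sigma)
    tilt_d = denoise(tilt, p.sigma)
    art = artifact_split(ori_d, tilt_d)
    c_ori, c_tilt = correlation_maps(ori_d, tilt_d, art, p.ssim)
    src_o, src_t = (ori_d, tilt_d) if p.fuse_denoised else (ori, tilt)
    res = fuse(src_o, src_t, c_ori, c_tilt)

    metal_mask = None
    fused_vals = res.fused.values
    mask = res.mask
    if p.metal_threshold is not None and ori.units == "mu":
        metal_mask = ori.values >= p.metal_threshold
        if metal_mask.any():
            fused_vals = np.where(metal_mask, src_o.values, fused_vals)
            mask = mask | metal_mask
    fused = replace(res.fused, values=fused_vals)
    return MARResult(fused, mask, c_ori, c_tilt, art, p, metal_mask=metal_mask)


def atmar_pipeline(ori: ReconImage, tilt: ReconImage,
                   p: PipelineParams | None = None, *,
                   augment: ReconImage | None = None,
                   geom=None, second_pass: bool = True) -> MARResult:
    """AT-MAR: a second T-MAR pass against a sinogram-inpainting MAR image.

    Stage 1 is plain T-MAR on the two scans.  Stage 2 re-runs the workflow
    with the stage-1 result as the "ordinary" input and an inpainting-MAR
    image of the ordinary scan as the complementary input.  ``augment`` may
    supply that image directly (any external MAR result); otherwise it is
    computed as NMAR on the virtual sinogram of the ordinary scan, which
    requires ``geom``.  ``second_pass=False`` returns stage 1 unchanged.
    """
    p = p or PipelineParams()
    stage1 = tmar_pipeline(ori, tilt, p)
    if not second_pass:
        return stage1
    if augment is None:
        if geom is None:
            raise ValueError("need geom to compute the NMAR augment image "
                             "(or pass augment= directly)")
        from .baselines import nmar_from_image

        augment = nmar_from_image(ori, geom)
    p2 = replace(p, registration_check=False)
    res = tmar_pipeline(stage1.fused, augment, p2)
    return replace(res, stage1=stage1, augment=augment)
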