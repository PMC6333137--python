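"""Fan-beam forward projection and polychromatic intensity simulation.

The scan model follows a third-generation CT: an x-ray point source on a
circle of radius SID around the isocenter, an equiangular detector arc at SDD,
``n_views`` view angles uniformly covering 360 degrees.  A polychromatic
measurement is formed per detector bin as

    counts = i0 * sum_i w_i * exp(-L_i),

where ``L_i`` is the monochromatic line integral of the attenuation map at bin
energy ``E_i`` and ``w_i`` the spectral weight.  Beam hardening and, behind
metal, photon starvation emerge from this sum; Poisson noise acts on counts
and zero-mean Gaussian noise (variance 0.001 by default elsewhere) acts on the
log-transformed data.  Zero counts are clamped to one count before the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .phantoms import MaterialSlice
from .physics import Spectrum, attenuation

__all__ = [
    "FanBeamGeometry",
    "Sinogram",
    "IntensitySinogram",
    "forward_project",
    "project_materials",
    "simulate_polychromatic",
    "add_poisson",
    "log_transform",
    "add_gaussian",
    "virtual_sinogram",
    "backproject_adjoint",
    "noise_streams",
]

MM_PER_CM = 10.0


@dataclass(frozen=True)
class FanBeamGeometry:
    """Equiangular fan-beam scan geometry (distances in mm)."""

    sid_mm: float = 400.0
    sdd_mm: float = 1100.0
    n_views: int = 720
    n_channels: int = 729
    fov_radius_mm: float = 120.0
    channel_pitch: float | None = None  # rad; default sized to cover the FOV
    coverage_deg: float = 360.0
    step_fraction: float = 0.5  # ray sampling step as a fraction of pixel size

    def __post_init__(self):
        if not 0 < self.sid_mm < self.sdd_mm:
            raise ValueError("need sdd > sid > 0")
        if self.n_views < 1 or self.n_channels < 2:
            raise ValueError("need n_views >= 1 and n_channels >= 2")
        if self.fov_radius_mm <= 0 or self.fov_radius_mm >= self.sid_mm:
            raise ValueError("fov radius must lie in (0, sid)")
        if self.channel_pitch is None:
            fan = 2.04 * np.arcsin(self.fov_radius_mm / self.sid_mm)
            object.__setattr__(self, "channel_pitch", fan / (self.n_channels - 1))
        if self.fan_angle < 2 * np.arcsin(self.fov_radius_mm / self.sid_mm) - 1e-12:
            raise ValueError("detector arc does not cover the FOV")

    @property
    def fan_angle(self) -> float:
        return self.channel_pitch * (self.n_channels - 1)

    @property
    def gammas(self) -> np.ndarray:
        k = np.arange(self.n_channels) - (self.n_channels - 1) / 2
        return k * self.channel_pitch

    @property
    def betas(self) -> np.ndarray:
        return np.arange(self.n_views) * np.deg2rad(self.coverage_deg) / self.n_views

    @property
    def sid_cm(self) -> float:
        return self.sid_mm / MM_PER_CM

    @property
    def fov_cm(self) -> float:
        return self.fov_radius_mm / MM_PER_CM


@dataclass(frozen=True)
class Sinogram:
    """Log line-integral data, shape (n_views, n_channels)."""

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.geometry.n_views, self.geometry.n_channels):
            raise ValueError("sinogram shape does not match geometry")
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class IntensitySinogram:
    """Detected photon counts per bin with incident fluence ``i0``."""

    counts: np.ndarray
    i0: float
    geometry: FanBeamGeometry

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (self.geometry.n_views, self.geometry.n_channels):
            raise ValueError("counts shape does not match geometry")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)


def _image_and_pixel(img, pixel_size):
    if hasattr(img, "values") and hasattr(img, "pixel_size"):
        return np.ascontiguousarray(img.values, dtype=float), float(img.pixel_size)
    if pixel_size is None:
        raise ValueError("pixel_size required for a bare array image")
    return np.ascontiguousarray(img, dtype=float), float(pixel_size)


def _check_fov(img: np.ndarray, px: float, geom: FanBeamGeometry):
    n, m = img.shape
    ii, jj = np.nonzero(np.abs(img) > 1e-12)
    if ii.size == 0:
        return
    y = ((n - 1) / 2 - ii) * px
    x = (jj - (m - 1) / 2) * px
    rmax = float(np.max(np.hypot(x, y)))
    if rmax > geom.fov_cm + px:
        raise ValueError(
            f"image content extends to radius {rmax:.2f} cm, beyond the "
            f"{geom.fov_cm:.2f} cm FOV (truncation not supported)"
        )


def forward_project(img, geom: FanBeamGeometry, pixel_size: float | None = None) -> Sinogram:
    """Line integrals of an attenuation image along all source->channel rays.

    ``img`` is a 2-D array in 1/cm (or a ReconImage); the non-zero support
    must lie inside the FOV.  Ray-driven with bilinear sampling at a step of
    ``geom.step_fraction`` pixels.
    """
    arr, px = _image_and_pixel(img, pixel_size)
    _check_fov(arr, px, geom)
    vals = _kernels.fan_project(arr, px, geom.sid_cm, geom.gammas, geom.betas,
                                geom.fov_cm, geom.step_fraction * px)
    return Sinogram(vals, geom)


def project_materials(sl: MaterialSlice, geom: FanBeamGeometry) -> np.ndarray:
    """Per-material path lengths [cm], shape (n_materials, n_views, n_channels).

    Nearest-neighbor sampling of the categorical label image; air (label 0)
    rows are included so the result sums to the in-FOV ray length.
    """
    labels = np.ascontiguousarray(sl.labels, dtype=np.int64)
    return _kernels.fan_project_labels(
        labels, len(sl.materials), sl.spacing, geom.sid_cm, geom.gammas,
        geom.betas, geom.fov_cm, geom.step_fraction * sl.spacing)


def simulate_polychromatic(sl: MaterialSlice, sp: Spectrum, geom: FanBeamGeometry,
                           i0: float = 1e7) -> IntensitySinogram:
    """Noise-free polychromatic counts for a material slice.

    Sums Beer-Lambert transmission over the spectral bins with per-material
    attenuation at each bin energy.
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    counts = np.zeros((geom.n_views, geom.n_channels))
    if sl.texture is None:
        # label-path route: one projection pass shared by all bins
        mu = np.array([[attenuation(m, e) for e in sp.energies]
                       for m in sl.materials])
        # air contributes ~nothing and its in-FOV path length depends on the
        # FOV, not the object; treat it as vacuum
        for a in [i for i, m in enumerate(sl.materials) if m == "air"]:
            mu[a, :] = 0.0
        paths = project_materials(sl, geom)  # (n_mat, nv, nc)
        for b, w in enumerate(sp.weights):
            line = np.tensordot(mu[:, b], paths, axes=(0, 0))
            counts += w * np.exp(-line)
    else:
        from .phantoms import slice_mu_image

        for e, w in zip(sp.energies, sp.weights):
            line = forward_project(slice_mu_image(sl, e), geom,
                                   pixel_size=sl.spacing).values
            counts += w * np.exp(-line)
    return IntensitySinogram(counts * i0, i0, geom)


def noise_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Two independent RNG streams (Poisson, Gaussian) from one user seed."""
    ss = np.random.SeedSequence(seed)
    poisson_ss, gauss_ss = ss.spawn(2)
    return np.random.default_rng(poisson_ss), np.random.default_rng(gauss_ss)


def add_poisson(isino: IntensitySinogram, seed: int | np.random.Generator) -> IntensitySinogram:
    """Replace each count with a Poisson draw of the same mean (reproducible)."""
    rng = seed if isinstance(seed, np.random.Generator) else noise_streams(seed)[0]
    noisy = rng.poisson(isino.counts).astype(float)
    return IntensitySinogram(noisy, isino.i0, isino.geometry)


def log_transform(isino: IntensitySinogram) -> Sinogram:
    """Log line integrals ``ln(i0 / counts)``; zero counts clamp to 1 count."""
    counts = np.maximum(isino.counts, 1.0)
    return Sinogram(np.log(isino.i0 / counts), isino.geometry)


def add_gaussian(sino: Sinogram, variance: float = 0.001,
                 seed: int | np.random.Generator = 0) -> Sinogram:
    """Add i.i.d. zero-mean Gaussian noise of the given variance in log domain."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return sino
    rng = seed if isinstance(seed, np.random.Generator) else noise_streams(seed)[1]
    noise = rng.normal(0.0, np.sqrt(variance), size=sino.values.shape)
    return Sinogram(sino.values + noise, sino.geometry)


def virtual_sinogram(img, geom: FanBeamGeometry, pixel_size: float | None = None) -> Sinogram:
    """Forward projection of a reconstructed image (monochromatic model).

    Stands in for raw projection data when the scanner does not export it;
    input to the sinogram-inpainting MAR baselines.  Line integrals are
    linear, so noise excursions (including negative pixels) pass through;
    pixels outside the scan FOV (pure reconstruction noise) are zeroed.
    """
    arr, px = _image_and_pixel(img, pixel_size)
    n, m = arr.shape
    ii, jj = np.mgrid[0:n, 0:m]
    y = ((n - 1) / 2 - ii) * px
    x = (jj - (m - 1) / 2) * px
    arr = np.where(x * x + y * y <= geom.fov_cm ** 2, arr, 0.0)
    return forward_project(arr, geom, pixel_size=px)


def backproject_adjoint(sino: Sinogram, n: int, pixel_size: float) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` on an n x n grid (testing aid)."""
    g = sino.geometry
    return _kernels.fan_backproject_adjoint(
        np.ascontiguousarray(sino.values), pixel_size, n, n, g.sid_cm,
        g.gammas, g.betas, g.fov_cm, g.step_fraction * pixel_size)
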