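"""Fan-beam filtered backprojection (equiangular detector, full 360-deg scan).

Standard three-step FBP for equiangular fan data: (1) cosine weighting
``p' = p * D * cos(gamma)``, (2) convolution with the discrete equiangular
ramp kernel (Hann-apodized by default), (3) backprojection weighted by the
inverse squared source-to-pixel distance.  Output images are linear
attenuation in 1/cm; :func:`to_hu` converts to Hounsfield units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from . import _kernels
from .projection import Sinogram

__all__ = ["ReconImage", "fbp", "to_hu"]


@dataclass(frozen=True)
class ReconImage:
    """2-D reconstructed attenuation image with grid metadata."""

    values: np.ndarray
    pixel_size: float  # cm, square pixels
    tilt_deg: float = 0.0  # provenance: gantry tilt of the originating scan
    units: str = "mu"  # "mu" (1/cm) or "hu"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("image must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.units not in ("mu", "hu"):
            raise ValueError("units must be 'mu' or 'hu'")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _equiangular_kernel(n_channels: int, dg: float, apodization: str) -> np.ndarray:
    """rfft of the discrete equiangular ramp kernel, optionally Hann-windowed."""
    L = next_fast_len(4 * n_channels)
    g = np.zeros(L)
    g[0] = 1.0 / (8.0 * dg * dg)
    n = np.arange(1, n_channels)
    odd = n[n % 2 == 1]
    vals = -0.5 / (np.pi * np.sin(odd * dg)) ** 2
    g[odd] = vals
    g[L - odd] = vals
    G = rfft(g)
    if apodization == "hann":
        j = np.arange(G.size)
        G = G * 0.5 * (1.0 + np.cos(2.0 * np.pi * j / L))
    elif apodization != "ramp":
        raise ValueError("apodization must be 'hann' or 'ramp'")
    return G


def fbp(sino: Sinogram, n: int | None = None, pixel_size: float | None = None,
        apodization: str = "hann") -> ReconImage:
    """Reconstruct an attenuation image from a full-scan fan-beam sinogram.

    Parameters
    ----------
    sino : Sinogram
        Log line-integral data over a full 360-degree scan.
    n, pixel_size : optional grid spec
        Output grid is ``n x n`` with square pixels of ``pixel_size`` cm.
        Defaults: pixel sized so the grid spans the FOV diameter with n=256.
    apodization : "hann" (default) or "ramp"
        Hann smooths the ramp filter; pure ramp is sharper but noisier.
    """
    geom = sino.geometry
    if geom.coverage_deg < 360.0 - 1e-9:
        raise ValueError("FBP requires full 360-degree view coverage")
    if n is None:
        n = 256
    if pixel_size is None:
        pixel_size = 2.0 * geom.fov_cm / n
    dg = geom.channel_pitch
    D = geom.sid_cm

    p = sino.values * (D * np.cos(geom.gammas))[None, :]
    G = _equiangular_kernel(geom.n_channels, dg, apodization)
    L = 2 * (G.size - 1)
    q = irfft(rfft(p, L, axis=1) * G[None, :], L, axis=1)[:, : geom.n_channels]
    q *= dg

    img = _kernels.fan_backproject(np.ascontiguousarray(q), pixel_size, n, n,
                                   D, geom.gammas, geom.betas)
    return ReconImage(img, pixel_size, tilt_deg=0.0, units="mu")


def to_hu(img: ReconImage, mu_water: float) -> ReconImage:
    """Convert 1/cm attenuation to Hounsfield units: 1000*(mu-mu_w)/mu_w."""
    if img.units != "mu":
        raise ValueError("input must be in 1/cm attenuation units")
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    hu = 1000.0 * (img.values - mu_water) / mu_water
    return replace(img, values=hu, units="hu")
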