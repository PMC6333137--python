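"""X-ray physics: tube spectra and energy-dependent linear attenuation.

The simulator models a polychromatic beam as a small number of monochromatic
energy bins.  At 120 kVp with six bins the bin centers are 20, 40, 60, 80, 100
and 120 keV.  Bin weights come from a filtered-Kramers tungsten-anode continuum
(bremsstrahlung ``(E_max - E)/E`` attenuated by 2.5 mm of aluminium inherent
filtration) integrated over each bin; the aluminium attenuation curve is part
of the bundled attenuation table, so the weights are deterministic.

Linear attenuation coefficients are looked up in a bundled CSV (NIST
XCOM-derived, see ``data/attenuation.csv``) with log-log interpolation between
tabulated energies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "Spectrum",
    "make_spectrum",
    "attenuation",
    "effective_mu",
    "known_materials",
]

_FILTRATION_CM_AL = 0.25  # 2.5 mm inherent aluminium filtration


@dataclass(frozen=True)
class Spectrum:
    """Discrete x-ray spectrum: energy bins (keV) and fluence weights."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or w.shape != e.shape:
            raise ValueError("energies and weights must be 1-D and equal length")
        if e.size == 0:
            raise ValueError("spectrum needs at least one bin")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("weights must sum to a positive value")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / s)

    @property
    def n_bins(self) -> int:
        return self.energies.size

    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))


@lru_cache(maxsize=1)
def _load_table() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    table: dict[str, list[tuple[float, float]]] = {}
    path = resources.files("tiltmar.data").joinpath("attenuation.csv")
    with path.open("r") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    for mat, e, mu in rows[1:]:
        table.setdefault(mat, []).append((float(e), float(mu)))
    out = {}
    for mat, pairs in table.items():
        pairs.sort()
        e = np.array([p[0] for p in pairs])
        mu = np.array([p[1] for p in pairs])
        out[mat] = (e, mu)
    return out


def known_materials() -> tuple[str, ...]:
    """Names accepted by :func:`attenuation`."""
    return tuple(sorted(_load_table()))


def attenuation(material: str, energy) -> float | np.ndarray:
    """Linear attenuation coefficient mu [1/cm] at ``energy`` [keV].

    Log-log interpolation between tabulated energies.  ``energy`` may be a
    scalar or array; it must lie within the table range for ``material``.
    """
    table = _load_table()
    if material not in table:
        raise KeyError(
            f"unknown material {material!r}; known: {', '.join(sorted(table))}"
        )
    e_tab, mu_tab = table[material]
    e = np.asarray(energy, dtype=float)
    if np.any(e < e_tab[0]) or np.any(e > e_tab[-1]):
        raise ValueError(
            f"energy outside table range [{e_tab[0]}, {e_tab[-1]}] keV for {material}"
        )
    out = np.exp(np.interp(np.log(e), np.log(e_tab), np.log(mu_tab)))
    return float(out) if np.isscalar(energy) else out


def _continuum(kvp: float, energies: np.ndarray) -> np.ndarray:
    """Filtered-Kramers fluence density on an energy grid [keV]."""
    f = np.clip(kvp - energies, 0.0, None) / energies
    mu_al = attenuation("aluminum", energies)
    return f * np.exp(-mu_al * _FILTRATION_CM_AL)


def make_spectrum(kvp: float, n_bins: int) -> Spectrum:
    """Collapse a ``kvp`` tungsten spectrum onto ``n_bins`` energy bins.

    Bin centers sit at ``kvp * i / n_bins`` for i = 1..n_bins (so 120 kVp with
    six bins gives 20, 40, ..., 120 keV); each weight integrates the continuum
    over the half-bin-width neighbourhood of its center.  A single-bin spectrum
    degenerates to the continuum's fluence-weighted mean energy with weight 1.
    """
    if not 40 <= kvp <= 150:
        raise ValueError("kvp must lie in [40, 150]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > int(kvp // 10):
        raise ValueError(f"n_bins={n_bins} exceeds distinct-energy capacity for {kvp} kVp")
    grid = np.arange(10.0, kvp + 0.25, 0.5)
    dens = _continuum(kvp, grid)
    if n_bins == 1:
        e_mean = float(np.sum(grid * dens) / np.sum(dens))
        return Spectrum(np.array([e_mean]), np.array([1.0]))
    centers = kvp * np.arange(1, n_bins + 1) / n_bins
    half = kvp / (2 * n_bins)
    weights = np.empty(n_bins)
    for i, c in enumerate(centers):
        sel = (grid > c - half) & (grid <= c + half)
        weights[i] = dens[sel].sum()
    return Spectrum(centers, weights)


def effective_mu(material: str, sp: Spectrum) -> float:
    """Fluence-weighted mean attenuation [1/cm] over the spectrum's bins."""
    return float(np.sum(sp.weights * attenuation(material, sp.energies)))


@dataclass(frozen=True)
class AttenuationTable:
    """Per-material mu at each energy of a spectrum (convenience bundle)."""

    material: str
    energies: np.ndarray
    mu: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mu is None:
            object.__setattr__(self, "mu", attenuation(self.material, self.energies))
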