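"""Parametric voxel phantoms and oblique slicing.

Two phantoms are provided: a pelvis-like object (soft-tissue body ellipse,
sacrum and lateral bone structures, two bilateral metal rods of radius
0.85 cm) and a head-like object (tissue ellipse, gypsum skull ring and
gingiva block, two 0.6 cm metal rods).  Both emulate the situation where an
ordinary axial scan sees both implants along shared rays while a gantry-tilted
scan does not.

Geometry conventions (used by the projector and FBP alike):

* world origin at isocenter, coordinates in cm;
* label grids are ``(nz, ny, nx)``; in a 2-D slice row 0 is the most anterior
  row, i.e. image row index grows toward -y;
* tilt is realized as an oblique cutting plane through ``z0`` rotated about a
  horizontal axis: ``axis="x"`` (lateral, gantry tilt) keeps x in-plane,
  ``axis="y"`` keeps y in-plane (phantom rotated about its vertical axis).

Since a tilt about the lateral axis moves the cutting plane up/down with the
anterior-posterior coordinate, bilateral rods can only be separated by a tilt
if they differ in AP position and z-extent.  The default pelvis configuration
offsets the rods by +-2 cm AP and staggers their z-extents so that the 0-deg
axial slice contains both rods while any plane tilted by >= 10 deg misses one
of them; the default head configuration does the analogous thing at 15 deg
about the other axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VoxelPhantom",
    "MaterialSlice",
    "PelvisConfig",
    "HeadConfig",
    "make_pelvis_phantom",
    "make_head_phantom",
    "oblique_slice",
    "slice_mu_image",
]

AIR = 0


@dataclass(frozen=True)
class VoxelPhantom:
    """Labeled 3-D material grid, ``labels[(iz, iy, ix)]`` indexing materials.

    ``texture`` is an optional multiplicative attenuation modulation field
    (2-D, axially columnar) applied to the soft-tissue material classes: it
    emulates heterogeneous organ/soft-tissue structure, which matters for MAR
    methods that must synthesize sinogram data they cannot measure.
    """

    labels: np.ndarray  # (nz, ny, nx) small ints
    spacing: tuple[float, float, float]  # (dz, dy, dx) cm
    materials: tuple[str, ...]  # materials[label] = name; label 0 is air
    tilt_axis: str = "x"  # default rotation axis for oblique slicing
    texture: np.ndarray | None = None  # (ny, nx) multiplicative field, ~1

    def __post_init__(self):
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (nz, ny, nx)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.labels.max(initial=0) >= len(self.materials):
            raise ValueError("label references undefined material")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def z_coords(self) -> np.ndarray:
        nz = self.labels.shape[0]
        return (np.arange(nz) - (nz - 1) / 2) * self.spacing[0]


@dataclass(frozen=True)
class MaterialSlice:
    """2-D material-label cut of a phantom; the simulator's scan subject."""

    labels: np.ndarray  # (ny, nx)
    spacing: float  # in-plane pixel size, cm (square pixels)
    materials: tuple[str, ...]
    tilt_deg: float = 0.0
    texture: np.ndarray | None = None  # multiplicative mu field for tissue

    TEXTURED_MATERIALS = ("soft_tissue", "adipose", "water")

    def __post_init__(self):
        if self.labels.ndim != 2:
            raise ValueError("slice labels must be 2-D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not -30 <= self.tilt_deg <= 30:
            raise ValueError("tilt_deg must lie in [-30, 30]")
        if self.labels.max(initial=0) >= len(self.materials):
            raise ValueError("label references undefined material")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class Rod:
    """Vertical cylindrical insert: center (x, y) cm, radius cm, z-extent cm."""

    x: float
    y: float
    radius: float
    z_min: float
    z_max: float


@dataclass(frozen=True)
class PelvisConfig:
    """Adult-pelvis-like dimensions: ~33 x 19 cm body on a 38.4 cm field."""

    n_xy: int = 256
    n_z: int = 72
    spacing_xy: float = 0.15  # cm
    spacing_z: float = 0.1  # cm
    body_axes: tuple[float, float] = (16.5, 9.5)  # semi-axes (x, y) cm
    sacrum_center: tuple[float, float] = (0.0, -5.5)
    sacrum_axes: tuple[float, float] = (3.2, 2.2)
    # each implant is embedded in a femoral bone cylinder around the rod site,
    # so the metal trace crosses dense bone edges as it does clinically
    femur_radius: float = 1.9
    rod_radius: float = 0.85  # cm
    # AP offsets and staggered z-extents realize the tilt separation (see module
    # docstring): at 10 deg about the lateral axis the plane is at
    # z = z0 + y*tan(10) = -/+0.353 cm at the rods, inside rod_left's extent but
    # above rod_right's top.
    rods: tuple[Rod, ...] = (
        Rod(x=-8.0, y=-2.0, radius=0.85, z_min=-0.7, z_max=3.2),
        Rod(x=8.0, y=2.0, radius=0.85, z_min=-3.2, z_max=0.1),
    )
    metal: str = "steel"
    # low-contrast internal anatomy (subcutaneous fat layer, visceral fat
    # pockets, a fluid-filled bladder): real pelvic soft tissue is not
    # piecewise constant, which matters for class-prior MAR methods
    fat_layer_thickness: float = 1.2  # cm, 0 disables
    fat_pockets: tuple[tuple[float, float, float, float], ...] = (
        (-4.0, -2.5, 1.8, 1.2), (4.0, -2.5, 1.8, 1.2))  # (cx, cy, ax, ay)
    bladder: tuple[float, float, float, float] = (0.0, 1.5, 3.0, 2.0)
    # bowel/rectal gas: sharp high-contrast structures that sinogram
    # interpolation cannot synthesize
    gas_pockets: tuple[tuple[float, float, float, float], ...] = (
        (0.0, -3.2, 1.1, 0.8), (-3.4, 1.8, 1.0, 0.7), (3.6, 2.3, 0.8, 0.6))
    # correlated soft-tissue heterogeneity (organ texture); deterministic
    # given the seed, axially columnar
    texture_amplitude: float = 0.05  # relative mu modulation (1 sigma)
    texture_corr_cm: float = 0.8
    texture_seed: int = 7
    materials: tuple[str, ...] = ("air", "soft_tissue", "adipose", "water",
                                  "bone", "steel")


@dataclass(frozen=True)
class HeadConfig:
    n_xy: int = 256
    n_z: int = 72
    spacing_xy: float = 0.1
    spacing_z: float = 0.1
    head_axes: tuple[float, float] = (8.0, 10.0)
    skull_thickness: float = 0.7  # cm, gypsum ring inside the head contour
    gingiva_center: tuple[float, float] = (0.0, 6.2)
    gingiva_axes: tuple[float, float] = (4.5, 2.2)
    rod_radius: float = 0.6
    # 15 deg about the y axis puts the plane at z = x*tan(15) = -/+0.402 cm at
    # the rods: inside rod_left, above rod_right.
    rods: tuple[Rod, ...] = (
        Rod(x=-1.5, y=6.2, radius=0.6, z_min=-0.7, z_max=2.5),
        Rod(x=1.5, y=6.2, radius=0.6, z_min=-2.5, z_max=0.25),
    )
    metal: str = "cerrobend"
    texture_amplitude: float = 0.03
    texture_corr_cm: float = 0.6
    texture_seed: int = 11
    materials: tuple[str, ...] = ("air", "soft_tissue", "gypsum", "cerrobend")

    def with_long_rods(self) -> "HeadConfig":
        """Rods spanning the full grid: a tilted slice still sees both (the
        'insufficient tilt' scenario)."""
        long = tuple(replace(r, z_min=-1e3, z_max=1e3) for r in self.rods)
        return replace(self, rods=long)


def _grid_xy(n: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    c = (n - 1) / 2
    x = (np.arange(n) - c) * spacing
    y = -(np.arange(n) - c) * spacing  # row 0 anterior (+y)
    return np.meshgrid(x, y, indexing="xy")


def _in_ellipse(x, y, cx, cy, ax, ay):
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _check_rods(rods, body_test):
    for i, r in enumerate(rods):
        if not body_test(r.x, r.y):
            raise ValueError(f"rod {i} center ({r.x}, {r.y}) lies outside the body")
    for i, a in enumerate(rods):
        for b in rods[i + 1:]:
            d = np.hypot(a.x - b.x, a.y - b.y)
            if d < a.radius + b.radius:
                raise ValueError("metal rods overlap each other")


def _make_texture(n: int, spacing: float, amplitude: float, corr_cm: float,
                  seed: int) -> np.ndarray | None:
    """Correlated multiplicative modulation field, mean 1, deterministic."""
    if amplitude <= 0:
        return None
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal((n, n)), corr_cm / spacing,
                        mode="wrap")
    f *= amplitude / f.std()
    return 1.0 + np.clip(f, -2.5 * amplitude, 2.5 * amplitude)


def _stack_with_rods(base: np.ndarray, rods, metal_label: int, x, y,
                     z: np.ndarray) -> np.ndarray:
    vol = np.repeat(base[None, :, :], z.size, axis=0)
    for r in rods:
        disk = (x - r.x) ** 2 + (y - r.y) ** 2 <= r.radius ** 2
        zsel = (z >= r.z_min) & (z <= r.z_max)
        vol[zsel] = np.where(disk, metal_label, vol[zsel])
    return vol


def make_pelvis_phantom(cfg: PelvisConfig | None = None) -> VoxelPhantom:
    """Pelvis-like phantom: tissue body, sacrum + lateral bones, two metal rods."""
    cfg = cfg or PelvisConfig()
    x, y = _grid_xy(cfg.n_xy, cfg.spacing_xy)
    tissue = cfg.materials.index("soft_tissue")
    bone = cfg.materials.index("bone")
    metal = cfg.materials.index(cfg.metal)

    base = np.full((cfg.n_xy, cfg.n_xy), AIR, dtype=np.int8)
    body = _in_ellipse(x, y, 0, 0, *cfg.body_axes)
    base[body] = tissue
    if cfg.fat_layer_thickness > 0:
        fat = cfg.materials.index("adipose")
        inner = _in_ellipse(x, y, 0, 0, cfg.body_axes[0] - cfg.fat_layer_thickness,
                            cfg.body_axes[1] - cfg.fat_layer_thickness)
        base[body & ~inner] = fat
        for cx, cy, ax_, ay_ in cfg.fat_pockets:
            base[_in_ellipse(x, y, cx, cy, ax_, ay_) & body] = fat
    if cfg.bladder is not None:
        water = cfg.materials.index("water")
        base[_in_ellipse(x, y, *cfg.bladder) & body] = water
    for cx, cy, ax_, ay_ in cfg.gas_pockets:
        base[_in_ellipse(x, y, cx, cy, ax_, ay_) & body] = AIR
    sac = _in_ellipse(x, y, *cfg.sacrum_center, *cfg.sacrum_axes)
    base[sac & body] = bone
    for r in cfg.rods:
        femur = (x - r.x) ** 2 + (y - r.y) ** 2 <= cfg.femur_radius ** 2
        base[femur & body] = bone

    _check_rods(cfg.rods, lambda rx, ry: _in_ellipse(rx, ry, 0, 0, *cfg.body_axes))
    z = (np.arange(cfg.n_z) - (cfg.n_z - 1) / 2) * cfg.spacing_z
    vol = _stack_with_rods(base, cfg.rods, metal, x, y, z)
    tex = _make_texture(cfg.n_xy, cfg.spacing_xy, cfg.texture_amplitude,
                        cfg.texture_corr_cm, cfg.texture_seed)
    return VoxelPhantom(vol, (cfg.spacing_z, cfg.spacing_xy, cfg.spacing_xy),
                        cfg.materials, tilt_axis="x", texture=tex)


def make_head_phantom(cfg: HeadConfig | None = None) -> VoxelPhantom:
    """Head-like phantom: tissue, gypsum skull ring and gingiva, metal rods."""
    cfg = cfg or HeadConfig()
    x, y = _grid_xy(cfg.n_xy, cfg.spacing_xy)
    tissue = cfg.materials.index("soft_tissue")
    gypsum = cfg.materials.index("gypsum")
    metal = cfg.materials.index(cfg.metal)

    base = np.full((cfg.n_xy, cfg.n_xy), AIR, dtype=np.int8)
    outer = _in_ellipse(x, y, 0, 0, *cfg.head_axes)
    inner = _in_ellipse(x, y, 0, 0, cfg.head_axes[0] - cfg.skull_thickness,
                        cfg.head_axes[1] - cfg.skull_thickness)
    base[inner] = tissue
    base[outer & ~inner] = gypsum
    ging = _in_ellipse(x, y, *cfg.gingiva_center, *cfg.gingiva_axes)
    base[ging & outer] = gypsum

    _check_rods(cfg.rods, lambda rx, ry: _in_ellipse(rx, ry, 0, 0, *cfg.head_axes))
    z = (np.arange(cfg.n_z) - (cfg.n_z - 1) / 2) * cfg.spacing_z
    vol = _stack_with_rods(base, cfg.rods, metal, x, y, z)
    tex = _make_texture(cfg.n_xy, cfg.spacing_xy, cfg.texture_amplitude,
                        cfg.texture_corr_cm, cfg.texture_seed)
    return VoxelPhantom(vol, (cfg.spacing_z, cfg.spacing_xy, cfg.spacing_xy),
                        cfg.materials, tilt_axis="y", texture=tex)


def oblique_slice(ph: VoxelPhantom, tilt_deg: float, z0: float = 0.0,
                  axis: str | None = None, registered: bool = False) -> MaterialSlice:
    """Cut a (possibly tilted) plane from the phantom by nearest-neighbor lookup.

    The plane passes through ``z0`` on the rotation axis and is rotated by
    ``tilt_deg`` about ``axis`` ("x" keeps the lateral direction in-plane, "y"
    the AP direction).  By default in-plane sampling keeps the phantom's
    transverse pixel size, so structures crossing the tilt direction appear
    foreshortened in world z exactly as in a tilted scan.  With
    ``registered=True`` the plane is instead sampled above the axial grid
    (pixel (i, j) maps to the same anatomical (x, y) as the axial slice, the
    plane height varying as ``z0 + c*tan(tilt)``): the ideal oblique-to-axial
    reformat, yielding a slice pixelwise co-registered with the 0-deg cut.
    Labels are sampled nearest-neighbor (they are categorical); points
    outside the grid read as air.
    """
    if not -30 <= tilt_deg <= 30:
        raise ValueError("tilt_deg must lie in [-30, 30]")
    axis = axis or ph.tilt_axis
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    nz, ny, nx = ph.shape
    dz, dy, dx = ph.spacing
    if abs(dy - dx) > 1e-12:
        raise ValueError("in-plane spacing must be isotropic")
    th = np.deg2rad(tilt_deg)
    cy_i, cx_i, cz_i = (ny - 1) / 2, (nx - 1) / 2, (nz - 1) / 2

    rows = np.arange(ny)
    cols = np.arange(nx)
    jj, ii = np.meshgrid(cols, rows)
    xw = (jj - cx_i) * dx
    yw = -(ii - cy_i) * dy  # row 0 anterior

    if axis == "x":
        v = yw  # in-plane coordinate along the tilted direction
        y3 = v if registered else v * np.cos(th)
        x3 = xw
    else:
        v = xw
        x3 = v if registered else v * np.cos(th)
        y3 = yw
    z3 = z0 + v * (np.tan(th) if registered else np.sin(th))

    iz = np.rint(z3 / dz + cz_i).astype(np.int64)
    iy = np.rint(cy_i - y3 / dy).astype(np.int64)
    ix = np.rint(x3 / dx + cx_i).astype(np.int64)
    inside = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    if not inside.any():
        raise ValueError("cutting plane misses the voxel grid")
    labels = np.full((ny, nx), AIR, dtype=ph.labels.dtype)
    labels[inside] = ph.labels[iz[inside], iy[inside], ix[inside]]
    tex = None
    if ph.texture is not None:
        tex = np.ones((ny, nx))
        tex[inside] = ph.texture[iy[inside], ix[inside]]
    return MaterialSlice(labels, dx, ph.materials, tilt_deg=tilt_deg, texture=tex)


def slice_mu_image(sl: MaterialSlice, energy: float) -> np.ndarray:
    """Monochromatic attenuation image [1/cm] of a material slice.

    Air reads as exactly zero; the soft-tissue classes are modulated by the
    phantom's texture field when present.
    """
    from . import physics

    lut = np.array([0.0 if m == "air" else physics.attenuation(m, energy)
                    for m in sl.materials])
    img = lut[sl.labels]
    if sl.texture is not None:
        textured = np.isin(sl.labels,
                           [i for i, m in enumerate(sl.materials)
                            if m in MaterialSlice.TEXTURED_MATERIALS])
        img = np.where(textured, img * sl.texture, img)
    return img
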