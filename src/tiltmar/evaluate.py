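"""ROI-based quantitative evaluation: mean absolute percentage error (MAPE).

MAPE is computed against an artifact-free reference image over soft-tissue
regions of interest, excluding the implants themselves:

    MAPE = 100 * mean_{ROI} |I - I_ref| / |I_ref|   [%]

The default ROI builder takes the phantom's soft-tissue label mask, erodes it
(away from anatomy edges) and removes a dilated metal neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion

from .phantoms import MaterialSlice
from .recon import ReconImage

__all__ = ["ROISet", "EvalReport", "mape", "compare", "soft_tissue_roi"]

_MU_WATER_60KEV = 0.206  # 1/cm, used to lift HU images onto a positive scale


@dataclass(frozen=True)
class ROISet:
    """Named binary evaluation masks (all must exclude metal pixels)."""

    masks: dict[str, np.ndarray]
    tissue_class: str = "soft_tissue"

    def __post_init__(self):
        if not self.masks:
            raise ValueError("ROISet needs at least one mask")
        for name, m in self.masks.items():
            if m.dtype != bool or not m.any():
                raise ValueError(f"ROI {name!r} must be a nonempty boolean mask")

    def union(self) -> np.ndarray:
        out = np.zeros_like(next(iter(self.masks.values())))
        for m in self.masks.values():
            out |= m
        return out


@dataclass(frozen=True)
class EvalReport:
    """MAPE per method, ascending; serializable to CSV."""

    rows: tuple[tuple[str, float], ...]
    roi_id: str = "soft_tissue"
    reference_id: str = "artifact_free"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["method", "mape_percent"])

    def to_csv(self, path=None) -> str | None:
        frame = self.to_frame()
        if path is None:
            buf = StringIO()
            frame.to_csv(buf, index=False)
            return buf.getvalue()
        frame.to_csv(path, index=False)
        return None

    def __getitem__(self, method: str) -> float:
        for name, v in self.rows:
            if name == method:
                return v
        raise KeyError(method)


def _positive_scale(img: ReconImage) -> np.ndarray:
    """Image values on a strictly positive-reference scale (mu domain)."""
    if img.units == "hu":
        return (img.values / 1000.0 + 1.0) * _MU_WATER_60KEV
    return img.values


def mape(img: ReconImage, ref: ReconImage, roi: ROISet) -> float:
    """Mean absolute percentage error of ``img`` vs ``ref`` over the ROI union."""
    if img.shape != ref.shape:
        raise ValueError("image and reference shapes differ")
    if img.units != ref.units:
        raise ValueError("image and reference units differ")
    sel = roi.union()
    if sel.shape != ref.shape:
        raise ValueError("ROI shape does not match images")
    a = _positive_scale(img)[sel]
    r = _positive_scale(ref)[sel]
    if np.any(r == 0):
        raise ValueError("reference is zero inside the ROI; MAPE undefined")
    return float(100.0 * np.mean(np.abs(a - r) / np.abs(r)))


def compare(methods: dict[str, ReconImage], ref: ReconImage, roi: ROISet) -> EvalReport:
    """One MAPE row per named method image, sorted ascending (best first)."""
    rows = sorted(((name, mape(img, ref, roi)) for name, img in methods.items()),
                  key=lambda r: (r[1], r[0]))
    return EvalReport(tuple(rows), roi_id=roi.tissue_class)


def soft_tissue_roi(sl: MaterialSlice, erode: int = 2, metal_dilate: int = 3,
                    extra_metal: np.ndarray | None = None) -> ROISet:
    """Soft-tissue ROI from phantom ground truth.

    Erodes the soft-tissue label mask by ``erode`` pixels and removes the
    metal mask dilated by ``metal_dilate`` pixels (blooming margin).
    ``extra_metal`` adds segmented metal from reconstructions (e.g. when the
    tilted slice shows metal at slightly different positions).
    """
    tissue_classes = [i for i, m in enumerate(sl.materials)
                      if m in ("soft_tissue", "adipose", "water")]
    metal_labels = [i for i, m in enumerate(sl.materials)
                    if m in ("steel", "titanium", "cerrobend")]
    tissue = np.isin(sl.labels, tissue_classes)
    if erode > 0:
        tissue = binary_erosion(tissue, iterations=erode)
    metal = np.isin(sl.labels, metal_labels)
    if extra_metal is not None:
        metal |= extra_metal
    if metal.any() and metal_dilate > 0:
        metal = binary_dilation(metal, iterations=metal_dilate)
    roi = tissue & ~metal
    if not roi.any():
        raise ValueError("soft-tissue ROI is empty")
    return ROISet({"soft_tissue": roi})
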