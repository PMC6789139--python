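"""Axon-density scoring in target ROIs.

Terminal-field images are background subtracted (white top-hat), binarized at
a pixel-intensity threshold held constant across all samples in a comparison,
and scored as percent coverage of a manually drawn region of interest:
100 * (positive pixels in ROI) / (total pixels in ROI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.morphology import disk, white_tophat

__all__ = [
    "ROI",
    "CoverageResult",
    "ThresholdMismatchError",
    "subtract_background",
    "binarize",
    "coverage",
    "score_sections",
]


class ThresholdMismatchError(ValueError):
    """Per-sample thresholds differ within one comparison set."""


@dataclass
class ROI:
    """Named ROI: a half-open pixel box (r0, c0, r1, c1) or a polygon."""

    name: str
    box: tuple[int, int, int, int] | None = None
    polygon: list[tuple[float, float]] | None = None  # (row, col) vertices
    section_id: str = ""

    def __post_init__(self) -> None:
        if (self.box is None) == (self.polygon is None):
            raise ValueError("give exactly one of box or polygon")
        if self.box is not None:
            r0, c0, r1, c1 = self.box
            if r1 <= r0 or c1 <= c0:
                raise ValueError("box must have positive area")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.box is not None:
            r0, c0, r1, c1 = self.box
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
                raise ValueError(f"ROI {self.name!r} exceeds the raster bounds")
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            return m
        m = polygon2mask(shape, np.asarray(self.polygon, dtype=float))
        if not m.any():
            raise ValueError(f"ROI {self.name!r} has empty area")
        return m


@dataclass
class CoverageResult:
    roi_name: str
    positive_px: int
    total_px: int
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.positive_px > self.total_px:
            raise ValueError("positive pixels cannot exceed ROI area")
        if not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError("coverage must lie in [0, 100]")


def subtract_background(img: np.ndarray, radius: int = 5) -> np.ndarray:
    """White top-hat with a disk footprint; flattens slowly varying background.

    Structures narrower than the disk (fibers) pass through; a constant
    offset is removed entirely.  Output is nonnegative by construction.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return white_tophat(np.asarray(img, dtype=float), footprint=disk(radius))


def binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    """Fixed-threshold mask: intensity >= threshold."""
    return np.asarray(img, dtype=float) >= float(threshold)


def coverage(mask: np.ndarray, roi: ROI) -> CoverageResult:
    """Percent of ROI pixels that are positive, to 2 decimals."""
    roi_mask = roi.to_mask(mask.shape)
    total = int(roi_mask.sum())
    if total == 0:
        raise ValueError(f"ROI {roi.name!r} has zero area")
    pos = int((mask & roi_mask).sum())
    return CoverageResult(roi_name=roi.name, positive_px=pos, total_px=total,
                          coverage_pct=round(100.0 * pos / total, 2))


def score_sections(sections: dict[str, np.ndarray], rois: list[ROI],
                   threshold: float | dict[str, float], radius: int = 5
                   ) -> pd.DataFrame:
    """Score every ROI against its section; one threshold per comparison set.

    ``threshold`` may be a scalar or a per-section mapping; a mapping whose
    values differ raises :class:`ThresholdMismatchError`, because the
    comparison logic depends on a threshold held constant across samples.
    """
    if isinstance(threshold, dict):
        vals = set(threshold.values())
        if len(vals) > 1:
            raise ThresholdMismatchError(
                f"thresholds differ within one comparison set: {sorted(vals)}")
        thr = vals.pop()
    else:
        thr = float(threshold)
    rows = []
    masks: dict[str, np.ndarray] = {}
    for sid, img in sections.items():
        masks[sid] = binarize(subtract_background(img, radius), thr)
    for roi in rois:
        sid = roi.section_id
        if sid not in masks:
            raise KeyError(f"ROI {roi.name!r} references unknown section {sid!r}")
        res = coverage(masks[sid], roi)
        rows.append({"section": sid, "roi": res.roi_name, "threshold": thr,
                     "positive_px": res.positive_px, "total_px": res.total_px,
                     "coverage_pct": res.coverage_pct})
    return pd.DataFrame(rows)
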