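"""Physical-unit measurements from annotated dermoscopic images.

A dermoscopic photograph carries a millimetre scale; two annotated pixel
positions on that scale plus the physical distance between them give the
pixel-to-millimetre conversion factor. Lesion and pigment extents arrive as
binary masks drawn by a dermatologist; areas are foreground pixel counts
scaled by mm_per_px**2, and the headline quantity is the Pigmentation
Coverage Ratio

    PCR (%) = 100 * pigmented area (mm^2) / total lesion area (mm^2).

Contour extraction and the shoelace polygon area are kept as a documented
cross-check on the pixel-count areas, not as the primary measurement: pixel
counting is exact on masks and orientation-free.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

__all__ = [
    "Calibration",
    "ChannelBounds",
    "AnnotatedLesionImage",
    "LesionMeasurement",
    "CalibrationError",
    "UndefinedPCRError",
    "compute_calibration",
    "read_calibration_sidecar",
    "write_calibration_sidecar",
    "mask_area_mm2",
    "extract_contours",
    "shoelace_area",
    "threshold_pigment",
    "pigmentation_coverage",
]

logger = logging.getLogger(__name__)

# 8-connected foreground for components and contours.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


class CalibrationError(ValueError):
    """Invalid calibration input (coincident points, nonpositive distance)."""


class UndefinedPCRError(ValueError):
    """PCR is undefined because the lesion mask is empty."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre conversion derived from an embedded scale."""

    mm_per_px: float
    source_points_px: tuple[tuple[float, float], tuple[float, float]]
    known_mm: float


@dataclass(frozen=True)
class ChannelBounds:
    """Inclusive per-channel intensity windows for colour thresholding."""

    r: tuple[int, int]
    g: tuple[int, int]
    b: tuple[int, int]

    def __post_init__(self) -> None:
        for lo, hi in (self.r, self.g, self.b):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"invalid channel bounds ({lo}, {hi})")

    @classmethod
    def full(cls) -> "ChannelBounds":
        return cls((0, 255), (0, 255), (0, 255))


@dataclass(frozen=True)
class LesionMeasurement:
    id: str
    lesion_area_mm2: float
    pigment_area_mm2: float
    pcr_percent: float


@dataclass
class AnnotatedLesionImage:
    """An RGB image with lesion/pigment masks and its calibration."""

    image: np.ndarray
    lesion_mask: np.ndarray
    pigment_mask: np.ndarray
    calibration: Calibration
    id: str = ""

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        hw = self.image.shape[:2]
        if self.lesion_mask.shape != hw or self.pigment_mask.shape != hw:
            raise ValueError("masks must match the image dimensions")
        lesion = as_bool_mask(self.lesion_mask)
        pigment = as_bool_mask(self.pigment_mask)
        outside = pigment & ~lesion
        if outside.any():
            # hand annotations often overshoot the boundary; clip, don't reject
            logger.warning(
                "%s: %d pigment pixels outside the lesion mask were clipped",
                self.id or "<image>",
                int(outside.sum()),
            )
            pigment = pigment & lesion
        self.lesion_mask = (lesion * 255).astype(np.uint8)
        self.pigment_mask = (pigment * 255).astype(np.uint8)

    @classmethod
    def load(
        cls,
        image_path: str | Path,
        lesion_mask_path: str | Path,
        pigment_mask_path: str | Path,
        sidecar_path: str | Path,
        id: str | None = None,
    ) -> "AnnotatedLesionImage":
        image = np.asarray(Image.open(image_path).convert("RGB"))
        lesion = np.asarray(Image.open(lesion_mask_path).convert("L"))
        pigment = np.asarray(Image.open(pigment_mask_path).convert("L"))
        cal = read_calibration_sidecar(sidecar_path)
        return cls(
            image=image,
            lesion_mask=lesion,
            pigment_mask=pigment,
            calibration=cal,
            id=id if id is not None else Path(image_path).stem,
        )


def as_bool_mask(mask: np.ndarray) -> np.ndarray:
    """Interpret any 2-D array as a binary mask (nonzero = foreground)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool) if mask.dtype == bool else mask > 0


def compute_calibration(
    point_a_px: Sequence[float],
    point_b_px: Sequence[float],
    known_mm: float,
) -> Calibration:
    """Conversion factor from two scale-bar endpoints a known distance apart."""
    ax, ay = float(point_a_px[0]), float(point_a_px[1])
    bx, by = float(point_b_px[0]), float(point_b_px[1])
    if known_mm <= 0:
        raise CalibrationError("known_mm must be positive")
    dist = math.hypot(ax - bx, ay - by)
    if dist == 0.0:
        raise CalibrationError("calibration points are coincident")
    return Calibration(
        mm_per_px=known_mm / dist,
        source_points_px=((ax, ay), (bx, by)),
        known_mm=float(known_mm),
    )


def read_calibration_sidecar(path: str | Path) -> Calibration:
    """Read a calibration sidecar JSON: two scale points and their distance."""
    with open(path) as fh:
        data = json.load(fh)
    return compute_calibration(data["point_a_px"], data["point_b_px"], data["known_mm"])


def write_calibration_sidecar(
    path: str | Path,
    point_a_px: Sequence[float],
    point_b_px: Sequence[float],
    known_mm: float,
    image_filename: str,
) -> None:
    payload = {
        "point_a_px": [float(point_a_px[0]), float(point_a_px[1])],
        "point_b_px": [float(point_b_px[0]), float(point_b_px[1])],
        "known_mm": float(known_mm),
        "image": image_filename,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def mask_area_mm2(mask: np.ndarray, cal: Calibration) -> float:
    """Mask area in mm^2: foreground pixel count times mm_per_px squared."""
    n = int(as_bool_mask(mask).sum())
    return n * cal.mm_per_px**2


def extract_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Outer boundary of each 8-connected foreground component.

    Returns one (k, 2) float array of (row, col) vertices per component,
    traced at the half-intensity level of the padded component, so each
    polygon is closed and encloses the component's pixel centres.
    """
    fg = as_bool_mask(mask)
    labels, n = ndimage.label(fg, structure=_STRUCTURE_8)
    contours: list[np.ndarray] = []
    for i in range(1, n + 1):
        comp = np.pad(labels == i, 1).astype(float)
        candidates = measure.find_contours(comp, 0.5)
        # outer boundary = longest closed contour of the component
        outer = max(candidates, key=lambda c: len(c))
        contours.append(outer - 1.0)  # undo padding offset
    return contours


def shoelace_area(polygon: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon given as (row, col) vertices."""
    p = np.asarray(polygon, dtype=float)
    y, x = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def threshold_pigment(
    image: np.ndarray,
    pigment_annotation_mask: np.ndarray,
    bounds: ChannelBounds,
) -> np.ndarray:
    """Colour-refine an annotated pigment mask.

    Keeps only annotated pixels whose every channel lies inside its inclusive
    window — the annotation restricts where pigment may be, the colour window
    decides which of those pixels actually count.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    ann = as_bool_mask(pigment_annotation_mask)
    if ann.shape != image.shape[:2]:
        raise ValueError("mask dimensions do not match the image")
    windows = (bounds.r, bounds.g, bounds.b)
    in_band = np.ones(image.shape[:2], dtype=bool)
    for ch, (lo, hi) in enumerate(windows):
        band = image[:, :, ch]
        in_band &= (band >= lo) & (band <= hi)
    return ((ann & in_band) * 255).astype(np.uint8)


def pigmentation_coverage(
    annotated: AnnotatedLesionImage,
    bounds: ChannelBounds | None = None,
) -> LesionMeasurement:
    """Lesion and pigment areas in mm^2 and the PCR (%).

    With ``bounds`` the pigment annotation is colour-refined first; without,
    the raw annotation is measured as drawn.
    """
    lesion = as_bool_mask(annotated.lesion_mask)
    if not lesion.any():
        raise UndefinedPCRError(f"{annotated.id or '<image>'}: empty lesion mask, PCR undefined")
    if bounds is None:
        pigment = as_bool_mask(annotated.pigment_mask)
    else:
        pigment = as_bool_mask(threshold_pigment(annotated.image, annotated.pigment_mask, bounds))
    cal = annotated.calibration
    lesion_mm2 = mask_area_mm2(lesion, cal)
    pigment_mm2 = mask_area_mm2(pigment, cal)
    return LesionMeasurement(
        id=annotated.id,
        lesion_area_mm2=lesion_mm2,
        pigment_area_mm2=pigment_mm2,
        pcr_percent=100.0 * pigment_mm2 / lesion_mm2,
    )
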