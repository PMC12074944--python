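"""Synthetic dermoscopy-like inputs with exact ground truth.

Three generators back the measurement and statistics layers:

* :func:`generate_lesion_image` draws a dermoscopy-style RGB image — a skin
  background, a smooth star-convex lesion (ellipse perturbed by low-order
  radial harmonics), blue-gray pigment blobs inside it, and a scale bar of
  known physical length whose endpoints go into a calibration sidecar. The
  emitted masks ARE the ground truth, so area and coverage recovery can be
  checked to the pixel.
* :func:`generate_cohort` simulates lesion-level clinical records with a
  chosen depth-layer mix, per-layer pigmentation drawn from a scaled Beta
  moment-matched to the layer's mean and SD, lognormal areas and
  per-size-class Bernoulli feature flags. Defaults reproduce the
  published 42-lesion cohort's summary statistics.
* :func:`infer_group_sizes` / :func:`reconstruct_contingency` invert printed
  group percentages back to the unique integer counts that produced them,
  turning published summary tables into re-testable contingency tables.

Percentages are matched under half-away-from-zero rounding to two decimals,
the convention used when the tables were printed (5/24 -> 20.83).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from . import reference
from .cohort import LesionRecord, classify_size
from .imaging import AnnotatedLesionImage, compute_calibration, write_calibration_sidecar
from .stats import ContingencyTable

__all__ = [
    "SynthImageParams",
    "GroundTruth",
    "CohortSimParams",
    "PrintedRow",
    "GenerationError",
    "InconsistencyError",
    "AmbiguityError",
    "PIGMENT_RGB",
    "LESION_RGB",
    "SKIN_RGB",
    "generate_lesion_image",
    "save_annotated_image",
    "generate_cohort",
    "infer_group_sizes",
    "reconstruct_contingency",
    "printed_rows_from_reference",
]

# Colour palette (RGB). The pigment tone sits in the blue-gray band that
# colour thresholding targets; the surround is kept well outside that band.
PIGMENT_RGB = (100, 110, 130)
LESION_RGB = (172, 118, 96)
SKIN_RGB = (225, 196, 178)
SCALE_BAR_RGB = (20, 20, 20)

_SCALE_ZONE_ROWS = 40  # top strip reserved for the scale bar, never lesion


class GenerationError(ValueError):
    """The requested synthetic image cannot be generated (e.g. lesion too big)."""


class InconsistencyError(ValueError):
    """No integer counts reproduce the printed percentages."""


class AmbiguityError(ValueError):
    """More than one integer solution reproduces the printed percentages."""

    def __init__(self, message: str, candidates: list):
        super().__init__(message)
        self.candidates = candidates


@dataclass(frozen=True)
class SynthImageParams:
    """Parameters of one synthetic dermoscopic image."""

    image_width_px: int = 1024
    image_height_px: int = 1024
    mm_per_px: float = 0.05
    lesion_area_target_mm2: float = 30.0
    pigment_coverage_target: float = 0.25
    n_pigment_blobs: int = 6
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.lesion_area_target_mm2 <= 0:
            raise ValueError("lesion area target must be positive")
        if not 0.0 <= self.pigment_coverage_target <= 1.0:
            raise ValueError("pigment_coverage_target must be in [0, 1]")
        if self.n_pigment_blobs < 0:
            raise ValueError("n_pigment_blobs must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    lesion_area_px: int
    pigment_area_px: int

    @property
    def coverage_fraction(self) -> float:
        if self.lesion_area_px == 0:
            return 0.0
        return self.pigment_area_px / self.lesion_area_px


def _lesion_radius_fn(rng: np.random.Generator, aspect: float):
    """Radius-vs-angle function: perturbed ellipse, total perturbation <= 15%."""
    orders = np.arange(2, 7)
    amps = rng.uniform(-1.0, 1.0, size=orders.size)
    total = np.abs(amps).sum()
    if total > 0:
        amps *= 0.15 / total
    phases = rng.uniform(0.0, 2.0 * np.pi, size=orders.size)

    def radius(theta: np.ndarray, base: float) -> np.ndarray:
        # ellipse with semi-axes base*aspect, base/aspect
        a, b = base * aspect, base / aspect
        ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        pert = 1.0 + sum(
            amp * np.cos(k * theta + ph) for k, amp, ph in zip(orders, amps, phases)
        )
        return ell * pert

    return radius


def _rasterize_lesion(h, w, cy, cx, radius_fn, base) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    return dy * dy + dx * dx <= radius_fn(theta, base) ** 2


def generate_lesion_image(
    params: SynthImageParams,
) -> tuple[AnnotatedLesionImage, GroundTruth]:
    """Render one synthetic annotated lesion image with exact ground truth.

    The lesion mask lands within 5% of the target area (fixed-point radius
    adjustment), the pigment mask within 0.02 of the target coverage (binary
    search on a global blob-radius scale, coverage being monotone in it), and
    the scale bar stays disjoint from the lesion. Identical params give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height_px, params.image_width_px
    target_px = params.lesion_area_target_mm2 / params.mm_per_px**2

    # --- scale bar ------------------------------------------------------
    for known_mm in (10.0, 5.0, 2.0, 1.0, 0.5):
        bar_len = known_mm / params.mm_per_px
        if bar_len <= w - 20:
            break
    else:
        raise GenerationError("image too small for a scale bar")
    bar_row = 12
    bar_x0 = 8
    point_a = (float(bar_x0), float(bar_row))
    point_b = (float(bar_x0 + bar_len), float(bar_row))

    # --- lesion ---------------------------------------------------------
    cy = _SCALE_ZONE_ROWS + (h - _SCALE_ZONE_ROWS) / 2.0
    cx = w / 2.0
    aspect = rng.uniform(1.0, 1.3)
    radius_fn = _lesion_radius_fn(rng, aspect)
    base = np.sqrt(target_px / np.pi)
    # worst-case extent: ellipse major axis * max harmonic perturbation
    max_extent = base * max(aspect, 1.0 / aspect) * 1.15
    room = min(cx, w - cx, cy - _SCALE_ZONE_ROWS, h - cy) - 4
    if max_extent > room:
        raise GenerationError(
            f"lesion of {params.lesion_area_target_mm2} mm^2 at "
            f"{params.mm_per_px} mm/px does not fit in a {w}x{h} image"
        )
    lesion = _rasterize_lesion(h, w, cy, cx, radius_fn, base)
    for _ in range(6):
        area = int(lesion.sum())
        if area > 0 and abs(area - target_px) / target_px <= 0.02:
            break
        if area == 0:
            raise GenerationError("lesion rasterized to an empty mask")
        base *= np.sqrt(target_px / area)
        lesion = _rasterize_lesion(h, w, cy, cx, radius_fn, base)
    lesion_px = int(lesion.sum())
    if abs(lesion_px - target_px) / target_px > 0.05:
        raise GenerationError("could not match the lesion area target within 5%")

    # --- pigment blobs --------------------------------------------------
    f = params.pigment_coverage_target
    if f == 0.0:
        pigment = np.zeros_like(lesion)
    else:
        if params.n_pigment_blobs == 0:
            raise GenerationError("positive coverage target with zero pigment blobs")
        ys, xs = np.nonzero(lesion)
        idx = rng.integers(0, ys.size, size=params.n_pigment_blobs)
        centers = np.stack([ys[idx], xs[idx]], axis=1).astype(float)
        base_r = np.sqrt(f * lesion_px / (params.n_pigment_blobs * np.pi))
        radii = base_r * rng.uniform(0.7, 1.3, size=params.n_pigment_blobs)

        yy, xx = np.mgrid[0:h, 0:w]
        d2 = np.stack(
            [(yy - cyx) ** 2 + (xx - cxx) ** 2 for cyx, cxx in centers], axis=0
        )

        def coverage(scale: float) -> np.ndarray:
            blob = (d2 <= (scale * radii[:, None, None]) ** 2).any(axis=0)
            return blob & lesion

        lo, hi = 0.0, 1.0
        while coverage(hi).sum() < f * lesion_px and hi < 1e4:
            lo, hi = hi, hi * 2.0
        best = coverage(hi)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            m = coverage(mid)
            if m.sum() >= f * lesion_px:
                hi, best = mid, m
            else:
                lo = mid
            if abs(best.sum() / lesion_px - f) <= 0.005:
                break
        pigment = best
        if abs(pigment.sum() / lesion_px - f) > 0.02:
            raise GenerationError("could not match the pigment coverage target")

    # --- compose --------------------------------------------------------
    img = np.empty((h, w, 3), dtype=float)
    img[:] = SKIN_RGB
    img[lesion] = LESION_RGB
    img[pigment] = PIGMENT_RGB
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    # crisp scale bar on top of noise; endpoints are the sidecar's truth
    img[bar_row - 1 : bar_row + 2, bar_x0 : int(round(bar_x0 + bar_len)) + 1] = SCALE_BAR_RGB

    if (lesion[: _SCALE_ZONE_ROWS + 1]).any():
        raise GenerationError("lesion intersects the scale-bar zone")

    cal = compute_calibration(point_a, point_b, known_mm)
    annotated = AnnotatedLesionImage(
        image=img,
        lesion_mask=(lesion * 255).astype(np.uint8),
        pigment_mask=(pigment * 255).astype(np.uint8),
        calibration=cal,
        id=f"synthetic_{params.seed}",
    )
    truth = GroundTruth(lesion_area_px=lesion_px, pigment_area_px=int(pigment.sum()))
    return annotated, truth


def save_annotated_image(
    annotated: AnnotatedLesionImage, out_dir: str | Path, stem: str
) -> dict[str, Path]:
    """Write image/mask PNGs and the calibration sidecar; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}.png",
        "lesion_mask": out / f"{stem}_lesion_mask.png",
        "pigment_mask": out / f"{stem}_pigment_mask.png",
        "sidecar": out / f"{stem}_calibration.json",
    }
    Image.fromarray(annotated.image, mode="RGB").save(paths["image"])
    Image.fromarray(annotated.lesion_mask, mode="L").save(paths["lesion_mask"])
    Image.fromarray(annotated.pigment_mask, mode="L").save(paths["pigment_mask"])
    a, b = annotated.calibration.source_points_px
    write_calibration_sidecar(
        paths["sidecar"], a, b, annotated.calibration.known_mm, paths["image"].name
    )
    return paths


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _default_layer_probs() -> tuple[float, float, float]:
    n = reference.COHORT_TOTAL_LESIONS
    return tuple(reference.DEPTH_LAYER_COUNTS[l] / n for l in reference.DEPTH_LAYERS)


def _default_prevalence() -> dict[str, tuple[float, float, float]]:
    return {
        f: tuple(p / 100.0 for p in reference.SIZE_GROUP_PERCENTAGES[f])
        for f in reference.FEATURES
    }


def _lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


_AREA_LOG_MEAN, _AREA_LOG_SD = _lognormal_from_moments(
    reference.TUMOR_AREA_MEAN_MM2, reference.TUMOR_AREA_SD_MM2
)


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort simulation settings; defaults mirror the published cohort."""

    n_lesions: int = reference.COHORT_TOTAL_LESIONS
    layer_probs: tuple[float, float, float] = field(default_factory=_default_layer_probs)
    layer_pcr_means: tuple[float, float, float] = (17.86, 15.42, 11.69)
    layer_pcr_sds: tuple[float, float, float] = (14.78, 18.27, 11.15)
    area_log_mean: float = _AREA_LOG_MEAN
    area_log_sd: float = _AREA_LOG_SD
    feature_prevalence_by_size: Mapping[str, tuple[float, float, float]] = field(
        default_factory=_default_prevalence
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions <= 0:
            raise ValueError("n_lesions must be positive")
        if len(self.layer_probs) != 3 or any(not 0 <= p <= 1 for p in self.layer_probs):
            raise ValueError("layer_probs must be three probabilities")
        if abs(sum(self.layer_probs) - 1.0) > 1e-9:
            raise ValueError("layer_probs must sum to 1")
        if any(not 0 <= m <= 100 for m in self.layer_pcr_means):
            raise ValueError("layer PCR means must be in [0, 100]")
        if any(s < 0 for s in self.layer_pcr_sds):
            raise ValueError("layer PCR SDs must be nonnegative")
        for m, s in zip(self.layer_pcr_means, self.layer_pcr_sds):
            if s > 0 and not 0 < m < 100:
                raise ValueError("a layer with positive SD needs a mean strictly inside (0, 100)")
            if s > 0 and s * s >= m * (100.0 - m):
                raise ValueError(
                    f"PCR mean {m} with SD {s} is infeasible on [0, 100] "
                    "(requires SD^2 < mean * (100 - mean))"
                )
        for f, probs in self.feature_prevalence_by_size.items():
            if len(probs) != 3 or any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"invalid prevalence triple for {f}")


def _pcr_sample(rng: np.random.Generator, mean: float, sd: float) -> float:
    """PCR draw on [0, 100] with exactly the requested mean and SD.

    A scaled Beta distribution — the canonical law for a coverage fraction —
    whose shape parameters are moment-matched to (mean, sd). A zero SD gives
    the mean exactly. Moment matching keeps the configured per-layer means
    recoverable from simulated cohorts, which naive truncation of a normal
    would bias (a truncated normal cannot even realise SD > mean on [0, inf)).
    """
    if sd == 0:
        return float(mean)
    mu = mean / 100.0
    var = (sd / 100.0) ** 2
    k = mu * (1.0 - mu) / var - 1.0
    return float(100.0 * rng.beta(mu * k, (1.0 - mu) * k))


def generate_cohort(params: CohortSimParams) -> list[LesionRecord]:
    """Simulate a cohort of lesion records, reproducible under the seed."""
    rng = np.random.default_rng(params.seed)
    layers = reference.DEPTH_LAYERS
    site_names = list(reference.SITE_COUNTS)
    site_p = np.array(list(reference.SITE_COUNTS.values()), dtype=float)
    site_p /= site_p.sum()
    subtype_names = list(reference.SUBTYPE_COUNTS)
    subtype_p = np.array(list(reference.SUBTYPE_COUNTS.values()), dtype=float)
    subtype_p /= subtype_p.sum()
    size_index = {"small": 0, "medium": 1, "large": 2}

    records = []
    for i in range(params.n_lesions):
        layer_i = int(rng.choice(3, p=np.asarray(params.layer_probs)))
        layer = layers[layer_i]
        depth_cm = float(rng.choice(reference.DEPTH_CM_VALUES[layer]))
        pcr = _pcr_sample(rng, params.layer_pcr_means[layer_i], params.layer_pcr_sds[layer_i])
        area = float(rng.lognormal(params.area_log_mean, params.area_log_sd))
        size = classify_size(area)
        features = {
            f: bool(rng.random() < probs[size_index[size]])
            for f, probs in params.feature_prevalence_by_size.items()
        }
        records.append(
            LesionRecord(
                id=f"L{i + 1:04d}",
                site=str(rng.choice(site_names, p=site_p)),
                subtype=str(rng.choice(subtype_names, p=subtype_p)),
                depth_cm=depth_cm,
                area_mm2=area,
                pcr_percent=pcr,
                features=features,
            )
        )
    return records


# ---------------------------------------------------------------------------
# printed-percentage inversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrintedRow:
    """One feature's printed per-group percentages (two decimals)."""

    feature_name: str
    group_percentages: tuple[float, ...]

    @property
    def n_groups(self) -> int:
        return len(self.group_percentages)


def printed_rows_from_reference() -> list[PrintedRow]:
    """The published feature-by-size percentage rows as PrintedRow inputs."""
    return [
        PrintedRow(feature_name=f, group_percentages=tuple(reference.SIZE_GROUP_PERCENTAGES[f]))
        for f in reference.FEATURES
    ]


def _round2(numer: int, denom: int) -> Decimal:
    return (Decimal(100 * numer) / Decimal(denom)).quantize(Decimal("0.01"), ROUND_HALF_UP)


def _matching_counts(pct: float, n: int) -> list[int]:
    target = Decimal(str(pct))
    return [c for c in range(n + 1) if _round2(c, n) == target]


def _compositions(total: int, k: int):
    """Ordered compositions of `total` into k positive parts."""
    if k == 1:
        yield (total,)
        return
    for cuts in combinations(range(1, total), k - 1):
        prev = 0
        parts = []
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(total - prev)
        yield tuple(parts)


def infer_group_sizes(rows: Sequence[PrintedRow], total: int) -> tuple[int, ...]:
    """Recover group sizes from printed percentages by exhaustive search.

    Searches every composition of ``total`` into positive group sizes and
    keeps those under which every printed percentage in every row is the
    two-decimal rounding of some integer count. The solution must be unique.
    """
    if not rows:
        raise ValueError("no rows given")
    k = rows[0].n_groups
    if any(r.n_groups != k for r in rows):
        raise ValueError("all rows must have the same number of groups")
    if total < k:
        raise ValueError("total must be at least the number of groups")

    candidates = []
    for comp in _compositions(total, k):
        if all(
            all(_matching_counts(p, n) for p, n in zip(row.group_percentages, comp))
            for row in rows
        ):
            candidates.append(comp)
    if not candidates:
        raise InconsistencyError(
            f"no composition of {total} into {k} groups reproduces the printed percentages"
        )
    if len(candidates) > 1:
        raise AmbiguityError(
            f"{len(candidates)} compositions reproduce the printed percentages: {candidates}",
            candidates,
        )
    return candidates[0]


def reconstruct_contingency(row: PrintedRow, group_sizes: Sequence[int]) -> ContingencyTable:
    """Rebuild a (present, absent)-by-group table from one printed row.

    For each group the present count is the unique integer whose two-decimal
    percentage equals the printed value.
    """
    if row.n_groups != len(group_sizes):
        raise ValueError("group count mismatch")
    counts = []
    for pct, n in zip(row.group_percentages, group_sizes):
        matches = _matching_counts(pct, n)
        if not matches:
            raise InconsistencyError(
                f"{row.feature_name}: no count in 0..{n} prints as {pct:.2f}%"
            )
        if len(matches) > 1:
            raise AmbiguityError(
                f"{row.feature_name}: counts {matches} all print as {pct:.2f}% of {n}",
                matches,
            )
        counts.append((matches[0], n - matches[0]))
    return ContingencyTable.from_counts(counts)
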