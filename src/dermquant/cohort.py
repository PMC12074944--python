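"""Lesion-level classification and cohort summaries.

Lesions are binned by calibrated area into small (<= 15 mm^2), medium
((15, 50] mm^2) and large (> 50 mm^2) classes, and by histological invasion
depth into upper (UL, <= 0.2 cm), middle (ML, 0.3-0.4 cm) and lower
(LL, >= 0.5 cm) layers after rounding the depth to one decimal of a
centimetre (micrometer-read depths are one-decimal values; rounding makes
the bins total). Summaries mirror the clinical reporting style: feature
prevalence percentages to two decimals, pigmentation mean ± sample SD per
depth layer, and depth-pigmentation correlations per layer and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from . import stats
from .reference import DEPTH_LAYERS, FEATURES
from .stats import ContingencyTable, CorrelationResult

__all__ = [
    "SIZE_CLASSES",
    "LesionRecord",
    "LayerSummary",
    "DepthSummary",
    "classify_size",
    "classify_depth",
    "round_percent",
    "feature_prevalence",
    "summarize_by_depth",
    "records_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "feature_size_table",
    "feature_subtype_table",
]

SIZE_CLASSES: tuple[str, ...] = ("small", "medium", "large")

SITES = (
    "nose", "cheek", "upper_lip", "medial_canthus", "infraorbital",
    "ear", "vertex", "frontal", "neck", "axilla",
)
SUBTYPES = ("superficial", "nodular", "micronodular", "adenoid", "mixed", "infiltrative")


def classify_size(area_mm2: float) -> str:
    """Size class from lesion area: small <= 15 < medium <= 50 < large (mm^2)."""
    if area_mm2 <= 0:
        raise ValueError("lesion area must be positive")
    if area_mm2 <= 15:
        return "small"
    if area_mm2 <= 50:
        return "medium"
    return "large"


def classify_depth(depth_cm: float) -> str:
    """Depth layer from invasion depth in cm.

    The depth is first rounded half-away-from-zero to one decimal; the layer
    is UL for <= 0.2 cm, ML for 0.3-0.4 cm, LL for >= 0.5 cm.
    """
    if depth_cm <= 0:
        raise ValueError("depth must be positive")
    decis = int(Decimal(str(depth_cm)).scaleb(1).quantize(Decimal("1"), ROUND_HALF_UP))
    if decis <= 2:
        return "UL"
    if decis <= 4:
        return "ML"
    return "LL"


def round_percent(value: float) -> float:
    """Round a percentage to two decimals, half away from zero (report style)."""
    return float(Decimal(str(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class LesionRecord:
    """One lesion's clinical and dermoscopic row."""

    id: str
    site: str
    subtype: str
    depth_cm: float
    area_mm2: float
    pcr_percent: float
    features: Mapping[str, bool]
    depth_layer: str = field(default="")
    size_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if not 0 <= self.pcr_percent <= 100:
            raise ValueError("pcr_percent must be in [0, 100]")
        missing = [f for f in FEATURES if f not in self.features]
        if missing:
            raise ValueError(f"missing feature flags: {missing}")
        layer = classify_depth(self.depth_cm)
        size = classify_size(self.area_mm2)
        if self.depth_layer and self.depth_layer != layer:
            raise ValueError(
                f"depth_layer {self.depth_layer!r} inconsistent with depth {self.depth_cm} cm"
            )
        if self.size_class and self.size_class != size:
            raise ValueError(
                f"size_class {self.size_class!r} inconsistent with area {self.area_mm2} mm^2"
            )
        object.__setattr__(self, "depth_layer", layer)
        object.__setattr__(self, "size_class", size)
        object.__setattr__(self, "features", dict(self.features))


@dataclass(frozen=True)
class LayerSummary:
    n: int
    mean_pcr_percent: float | None
    sd_pcr_percent: float | None
    pearson: CorrelationResult
    spearman: CorrelationResult


@dataclass(frozen=True)
class DepthSummary:
    layers: dict[str, LayerSummary]
    pooled_pearson: CorrelationResult
    pooled_spearman: CorrelationResult
    n_total: int


def feature_prevalence(
    tables: Mapping[str, ContingencyTable],
) -> dict[str, dict[str, float | tuple[float, ...]]]:
    """Overall and per-group prevalence (%) from present/absent group tables.

    Each table has one row per group with columns (present, absent); all
    tables must share group sizes. Percentages are reported to two decimals.
    """
    if not tables:
        raise ValueError("no tables given")
    group_sizes = None
    out: dict[str, dict[str, float | tuple[float, ...]]] = {}
    for name, table in tables.items():
        if table.shape[1] != 2:
            raise ValueError(f"{name}: expected (present, absent) columns")
        sizes = table.row_margins
        if group_sizes is None:
            group_sizes = sizes
        elif sizes != group_sizes:
            raise ValueError(f"{name}: group sizes {sizes} differ from {group_sizes}")
        total = table.total
        if total == 0:
            raise ValueError(f"{name}: zero total")
        present = [row[0] for row in table.counts]
        out[name] = {
            "overall_percent": round_percent(100.0 * sum(present) / total),
            "group_percent": tuple(
                round_percent(100.0 * c / n) for c, n in zip(present, sizes)
            ),
        }
    return out


def summarize_by_depth(records: Sequence[LesionRecord]) -> DepthSummary:
    """Per-layer pigmentation mean ± SD and depth-PCR correlations.

    SD is None for layers with a single lesion; correlations are undefined
    (None estimate/p) below three lesions or under zero variance.
    """
    if not records:
        raise ValueError("no records")
    layers: dict[str, LayerSummary] = {}
    for layer in DEPTH_LAYERS:
        sub = [r for r in records if r.depth_layer == layer]
        depths = [r.depth_cm for r in sub]
        pcrs = [r.pcr_percent for r in sub]
        if sub:
            mean, sd = stats.mean_sd(pcrs)
        else:
            mean, sd = None, None
        layers[layer] = LayerSummary(
            n=len(sub),
            mean_pcr_percent=mean,
            sd_pcr_percent=sd,
            pearson=stats.pearson(depths, pcrs),
            spearman=stats.spearman(depths, pcrs),
        )
    depths = [r.depth_cm for r in records]
    pcrs = [r.pcr_percent for r in records]
    return DepthSummary(
        layers=layers,
        pooled_pearson=stats.pearson(depths, pcrs),
        pooled_spearman=stats.spearman(depths, pcrs),
        n_total=len(records),
    )


# ---------------------------------------------------------------------------
# cohort CSV schema: id,site,subtype,depth_cm,depth_layer,area_mm2,
#                    pcr_percent,<14 feature flags as 0/1>
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "site", "subtype", "depth_cm", "depth_layer", "area_mm2", "pcr_percent"] + list(FEATURES)


def records_to_frame(records: Iterable[LesionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "site": r.site,
            "subtype": r.subtype,
            "depth_cm": r.depth_cm,
            "depth_layer": r.depth_layer,
            "area_mm2": r.area_mm2,
            "pcr_percent": r.pcr_percent,
        }
        row.update({f: int(bool(r.features[f])) for f in FEATURES})
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[LesionRecord]:
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            LesionRecord(
                id=str(row["id"]),
                site=str(row["site"]),
                subtype=str(row["subtype"]),
                depth_cm=float(row["depth_cm"]),
                area_mm2=float(row["area_mm2"]),
                pcr_percent=float(row["pcr_percent"]),
                features={f: bool(int(row[f])) for f in FEATURES},
            )
        )
    return records


def write_cohort_csv(records: Iterable[LesionRecord], path: str | Path) -> None:
    # repr keeps float fields bit-exact through a CSV round trip
    records_to_frame(records).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_cohort_csv(path: str | Path) -> list[LesionRecord]:
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))


def _present_absent_table(
    records: Sequence[LesionRecord],
    feature: str,
    group_of: "Literal['size_class', 'subtype']",
    groups: Sequence[str],
) -> ContingencyTable:
    counts = []
    for g in groups:
        sub = [r for r in records if getattr(r, group_of) == g]
        present = sum(bool(r.features[feature]) for r in sub)
        counts.append((present, len(sub) - present))
    return ContingencyTable.from_counts(counts)


def feature_size_table(records: Sequence[LesionRecord], feature: str) -> ContingencyTable:
    """Present/absent counts of one feature across occupied size classes."""
    groups = [g for g in SIZE_CLASSES if any(r.size_class == g for r in records)]
    return _present_absent_table(records, feature, "size_class", groups)


def feature_subtype_table(records: Sequence[LesionRecord], feature: str) -> ContingencyTable:
    """Present/absent counts of one feature across occupied subtypes."""
    groups = [g for g in SUBTYPES if any(r.subtype == g for r in records)]
    return _present_absent_table(records, feature, "subtype", groups)
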