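"""Published summary tables of a 42-lesion facial BCC dermoscopy cohort.

The cohort itself (images and per-lesion records) is not publicly deposited;
what is available are its printed summary statistics: per-size-group and
overall prevalences of 14 dermoscopic features, depth-layer pigmentation
means and SDs, and clinical composition counts. These printed values are
data inputs here — they seed the synthetic cohort generator's defaults and,
via exact percentage inversion (:func:`dermquant.synth.infer_group_sizes` and
:func:`dermquant.synth.reconstruct_contingency`), they let the original
feature-by-size contingency tables be recovered and re-tested.
"""

from __future__ import annotations

COHORT_TOTAL_LESIONS = 42

#: Canonical order of the 14 dermoscopic feature flags.
FEATURES: tuple[str, ...] = (
    "blue_gray_dots_globules",
    "blue_gray_ovoid_nests",
    "maple_leaf",
    "spoke_wheel",
    "concentric",
    "arborizing_telangiectasia",
    "short_fine_telangiectasia",
    "multiple_erosions",
    "ulceration",
    "shiny_white_red_areas",
    "shiny_white_structures",
    "hemorrhage",
    "scale",
    "milia_like_cyst",
)

#: Feature prevalence (%) per tumor-size group (<=15, 16-50, >50 mm^2),
#: printed to two decimals.
SIZE_GROUP_PERCENTAGES: dict[str, tuple[float, float, float]] = {
    "blue_gray_dots_globules": (58.33, 69.23, 20.00),
    "blue_gray_ovoid_nests": (58.33, 61.54, 40.00),
    "maple_leaf": (79.17, 84.62, 60.00),
    "spoke_wheel": (37.50, 38.46, 60.00),
    "concentric": (25.00, 23.08, 40.00),
    "arborizing_telangiectasia": (70.83, 84.62, 40.00),
    "short_fine_telangiectasia": (83.33, 69.23, 100.00),
    "multiple_erosions": (62.50, 46.15, 60.00),
    "ulceration": (37.50, 46.15, 80.00),
    "shiny_white_red_areas": (33.33, 30.77, 60.00),
    "shiny_white_structures": (83.33, 69.23, 80.00),
    "hemorrhage": (20.83, 30.77, 80.00),
    "scale": (45.83, 30.77, 60.00),
    "milia_like_cyst": (50.00, 23.08, 20.00),
}

#: Overall feature prevalence (%) across the whole cohort.
OVERALL_PREVALENCE: dict[str, float] = {
    "blue_gray_ovoid_nests": 57.14,
    "blue_gray_dots_globules": 57.14,
    "maple_leaf": 78.57,
    "spoke_wheel": 40.48,
    "concentric": 26.19,
    "arborizing_telangiectasia": 71.43,
    "short_fine_telangiectasia": 80.95,
    "multiple_erosions": 57.14,
    "ulceration": 45.24,
    "shiny_white_red_areas": 35.71,
    "shiny_white_structures": 78.57,
    "hemorrhage": 30.95,
    "scale": 42.86,
    "milia_like_cyst": 38.10,
}

#: Tumor-depth layers: counts and pigmentation-coverage (%) mean ± SD.
#: Depth ranges in cm: UL 0.1-0.2, ML 0.3-0.4, LL 0.5+ (printed as 0.5-0.6).
DEPTH_LAYERS: tuple[str, ...] = ("UL", "ML", "LL")
DEPTH_LAYER_COUNTS: dict[str, int] = {"UL": 23, "ML": 12, "LL": 7}
DEPTH_LAYER_PCR_MEAN: dict[str, float] = {"UL": 17.86, "ML": 15.42, "LL": 11.69}
DEPTH_LAYER_PCR_SD: dict[str, float] = {"UL": 14.78, "ML": 18.27, "LL": 11.15}
DEPTH_CM_VALUES: dict[str, tuple[float, ...]] = {
    "UL": (0.1, 0.2),
    "ML": (0.3, 0.4),
    "LL": (0.5, 0.6),
}

#: Whole-cohort tumor area (mm^2): mean and SD.
TUMOR_AREA_MEAN_MM2 = 29.26
TUMOR_AREA_SD_MM2 = 28.14

#: Anatomical-site counts (n = 42 lesions); the six extra lesions beyond the
#: named facial sites are spread over ear/vertex/frontal/neck/axilla.
SITE_COUNTS: dict[str, int] = {
    "nose": 18,
    "cheek": 6,
    "upper_lip": 5,
    "medial_canthus": 4,
    "infraorbital": 4,
    "ear": 2,
    "vertex": 1,
    "frontal": 1,
    "neck": 1,
    "axilla": 1,
}

#: Histological subtype counts (n = 42 lesions).
SUBTYPE_COUNTS: dict[str, int] = {
    "superficial": 8,
    "nodular": 12,
    "micronodular": 1,
    "adenoid": 12,
    "mixed": 6,
    "infiltrative": 3,
}

#: Dermoscopic feature -> histopathological correlate (report annotation only).
HISTOPATHOLOGY_CORRELATES: dict[str, str] = {
    "blue_gray_ovoid_nests": "Basaloid tumor islands with peripheral palisading.",
    "blue_gray_dots_globules": "Melanin-laden basaloid cells and melanophages within the tumor mass.",
    "maple_leaf": "Pigmented basaloid tumor lobules extending into the dermis.",
    "spoke_wheel": "Radial arrangement of basaloid cells with high melanin content.",
    "concentric": "Irregular tumor nests surrounded by fibrotic stroma.",
    "arborizing_telangiectasia": "Dilated, tortuous blood vessels within the fibrotic tumor stroma.",
    "short_fine_telangiectasia": "Superficial vascular proliferation with minimal fibrosis.",
    "multiple_erosions": "Loss of epidermal integrity, with superficial ulceration.",
    "ulceration": "Deep epidermal loss with necrotic tumor debris.",
    "shiny_white_red_areas": "Stromal fibrosis and increased collagen deposition.",
    "shiny_white_structures": "Dense fibrosis in the dermis, associated with aggressive tumor behavior.",
    "hemorrhage": "Ruptured blood vessels and extravasated erythrocytes within the tumor stroma.",
    "scale": "Hyperkeratosis and parakeratosis due to chronic irritation.",
    "milia_like_cyst": "Keratin-filled cystic spaces within the tumor mass.",
}
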