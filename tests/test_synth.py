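"""Tests for synthetic image/cohort generation and percentage inversion."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dermquant.cohort import classify_depth, classify_size
from dermquant.synth import (
    AmbiguityError,
    CohortSimParams,
    GenerationError,
    InconsistencyError,
    PrintedRow,
    SynthImageParams,
    generate_cohort,
    generate_lesion_image,
    infer_group_sizes,
    printed_rows_from_reference,
    reconstruct_contingency,
    save_annotated_image,
)

SMALL = dict(image_width_px=256, image_height_px=256, mm_per_px=0.1, lesion_area_target_mm2=30.0)


class TestGenerateLesionImage:
    def test_zero_coverage_draws_no_pigment(self):
        _, truth = generate_lesion_image(
            SynthImageParams(**SMALL, pigment_coverage_target=0.0, n_pigment_blobs=0, seed=1)
        )
        assert truth.pigment_area_px == 0
        assert truth.coverage_fraction == 0.0

    def test_full_coverage_pigments_whole_lesion(self):
        annotated, truth = generate_lesion_image(
            SynthImageParams(**SMALL, pigment_coverage_target=1.0, n_pigment_blobs=3, seed=2)
        )
        assert truth.coverage_fraction == 1.0
        assert np.array_equal(annotated.pigment_mask, annotated.lesion_mask)

    def test_quarter_coverage_scenario(self):
        params = SynthImageParams(
            image_width_px=1024,
            image_height_px=1024,
            mm_per_px=0.05,
            lesion_area_target_mm2=30.0,
            pigment_coverage_target=0.25,
            seed=7,
        )
        _, truth = generate_lesion_image(params)
        assert 0.23 <= truth.coverage_fraction <= 0.27

    def test_lesion_area_within_five_percent_of_target(self):
        params = SynthImageParams(**SMALL, seed=3)
        _, truth = generate_lesion_image(params)
        target_px = params.lesion_area_target_mm2 / params.mm_per_px**2
        assert abs(truth.lesion_area_px - target_px) / target_px <= 0.05

    def test_mask_containment_and_scale_bar_disjoint(self):
        annotated, _ = generate_lesion_image(SynthImageParams(**SMALL, seed=4))
        lesion = annotated.lesion_mask > 0
        pigment = annotated.pigment_mask > 0
        assert not (pigment & ~lesion).any()
        # scale bar lives in the reserved top strip, which the lesion never enters
        assert not lesion[:40].any()

    def test_seed_determinism_bit_identical(self, tmp_path):
        params = SynthImageParams(**SMALL, seed=11)
        a1, t1 = generate_lesion_image(params)
        a2, t2 = generate_lesion_image(params)
        assert np.array_equal(a1.image, a2.image)
        assert np.array_equal(a1.lesion_mask, a2.lesion_mask)
        assert np.array_equal(a1.pigment_mask, a2.pigment_mask)
        assert t1 == t2
        p1 = save_annotated_image(a1, tmp_path / "a", "x")
        p2 = save_annotated_image(a2, tmp_path / "b", "x")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_lesion_too_large_rejected(self):
        with pytest.raises(GenerationError):
            generate_lesion_image(
                SynthImageParams(
                    image_width_px=128, image_height_px=128, mm_per_px=0.1,
                    lesion_area_target_mm2=500.0, seed=0,
                )
            )

    def test_positive_coverage_needs_blobs(self):
        with pytest.raises(GenerationError):
            generate_lesion_image(
                SynthImageParams(**SMALL, pigment_coverage_target=0.3, n_pigment_blobs=0, seed=0)
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SynthImageParams(**SMALL, pigment_coverage_target=1.5)
        with pytest.raises(ValueError):
            SynthImageParams(**SMALL, noise_sd=-1.0)


class TestGenerateCohort:
    def test_default_cohort_size_and_determinism(self):
        r1 = generate_cohort(CohortSimParams(seed=5))
        r2 = generate_cohort(CohortSimParams(seed=5))
        assert len(r1) == 42
        assert r1 == r2

    def test_depth_consistent_with_layer(self):
        for r in generate_cohort(CohortSimParams(n_lesions=300, seed=6)):
            assert classify_depth(r.depth_cm) == r.depth_layer
            assert classify_size(r.area_mm2) == r.size_class
            assert 0.0 <= r.pcr_percent <= 100.0

    def test_layer_counts_match_probabilities(self):
        records = generate_cohort(CohortSimParams(n_lesions=10_000, seed=7))
        frac = collections.Counter(r.depth_layer for r in records)
        for layer, p in zip(("UL", "ML", "LL"), (23 / 42, 12 / 42, 7 / 42)):
            se = (p * (1 - p) / 10_000) ** 0.5
            assert abs(frac[layer] / 10_000 - p) < 4 * se

    def test_zero_sd_gives_exact_layer_means(self):
        params = CohortSimParams(
            n_lesions=60, layer_pcr_means=(20.0, 15.0, 10.0), layer_pcr_sds=(0.0, 0.0, 0.0), seed=8
        )
        by_layer = {"UL": 20.0, "ML": 15.0, "LL": 10.0}
        for r in generate_cohort(params):
            assert r.pcr_percent == by_layer[r.depth_layer]

    def test_layer_pcr_moments_recovered_at_large_n(self):
        """Empirical per-layer PCR means and SDs sit within 3 standard errors
        of the configured values (and means within 0.5 pp) at n = 10000."""
        params = CohortSimParams(n_lesions=10_000, seed=9)
        records = generate_cohort(params)
        for i, layer in enumerate(("UL", "ML", "LL")):
            vals = np.array([r.pcr_percent for r in records if r.depth_layer == layer])
            mean, sd = params.layer_pcr_means[i], params.layer_pcr_sds[i]
            se_mean = sd / np.sqrt(vals.size)
            assert abs(vals.mean() - mean) < max(3 * se_mean, 1e-9)
            assert abs(vals.mean() - mean) < 0.5
            # SE of the sample SD under approximate normality: sd / sqrt(2(n-1))
            se_sd = sd / np.sqrt(2 * (vals.size - 1))
            assert abs(vals.std(ddof=1) - sd) < 3 * se_sd

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            CohortSimParams(layer_probs=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            CohortSimParams(layer_pcr_means=(50.0, 15.42, 11.69), layer_pcr_sds=(60.0, 18.27, 11.15))


class TestInferGroupSizes:
    def test_published_size_rows_give_unique_composition(self):
        assert infer_group_sizes(printed_rows_from_reference(), 42) == (24, 13, 5)

    def test_single_group_total(self):
        assert infer_group_sizes([PrintedRow("f", (100.00,))], 5) == (5,)

    def test_fifty_fifty_fifty_of_six_is_unique(self):
        # only (2,2,2) can print 50.00 in every group: odd groups and size-1/
        # size-4... only even group sizes admit an exact 50.00
        assert infer_group_sizes([PrintedRow("f", (50.00, 50.00, 50.00))], 6) == (2, 2, 2)

    def test_ambiguous_rows_raise_with_candidates(self):
        with pytest.raises(AmbiguityError) as exc:
            infer_group_sizes([PrintedRow("f", (50.00, 50.00))], 8)
        assert set(exc.value.candidates) == {(2, 6), (4, 4), (6, 2)}

    def test_inconsistent_percentages_raise(self):
        with pytest.raises(InconsistencyError):
            infer_group_sizes([PrintedRow("f", (33.00, 50.00))], 5)


class TestReconstructContingency:
    def test_published_hemorrhage_row(self):
        table = reconstruct_contingency(PrintedRow("hemorrhage", (20.83, 30.77, 80.00)), (24, 13, 5))
        assert table.counts == ((5, 19), (4, 9), (4, 1))

    def test_all_present(self):
        table = reconstruct_contingency(PrintedRow("f", (100.00, 100.00)), (6, 3))
        assert [r[0] for r in table.counts] == [6, 3]

    def test_none_present(self):
        table = reconstruct_contingency(PrintedRow("f", (0.00,)), (7,))
        assert table.counts == ((0, 7),)

    def test_unreproducible_percentage_raises(self):
        with pytest.raises(InconsistencyError):
            reconstruct_contingency(PrintedRow("f", (33.00,)), (3,))


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    sizes=st.lists(st.integers(1, 60), min_size=1, max_size=4),
    data=st.data(),
)
def test_percentage_print_reconstruct_round_trip(sizes, data):
    """Printing counts as two-decimal percentages and inverting them recovers
    the original counts for any small table."""
    from decimal import ROUND_HALF_UP, Decimal

    counts = [data.draw(st.integers(0, n)) for n in sizes]
    printed = tuple(
        float((Decimal(100 * c) / Decimal(n)).quantize(Decimal("0.01"), ROUND_HALF_UP))
        for c, n in zip(counts, sizes)
    )
    table = reconstruct_contingency(PrintedRow("f", printed), tuple(sizes))
    assert [r[0] for r in table.counts] == counts
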