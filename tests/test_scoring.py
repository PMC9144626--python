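"""Score definitions, Outer-invariance, KS statistic/p-value correctness
(including the exhaustive permutation oracle), and dataset-level scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylloseg import (
    MPMImage,
    OUTER,
    STROMA,
    EPITHELIAL,
    area_ratio,
    mean_shg_in_stroma,
    ks_two_sample,
    score_dataset,
)
from phylloseg.errors import EmptyInputError

from oracles import ks_statistic_loop, ks_exact_p_enumeration


def _mask(epithelial=0, stroma=0, outer=0):
    vals = [EPITHELIAL] * epithelial + [STROMA] * stroma + [OUTER] * outer
    side = int(np.ceil(np.sqrt(len(vals))))
    vals += [OUTER] * (side * side - len(vals))
    return np.array(vals, dtype=np.uint8).reshape(side, side)


class TestAreaRatio:
    def test_direct_counts(self):
        assert area_ratio(_mask(epithelial=100, stroma=400)) == pytest.approx(0.25)
        assert area_ratio(_mask(epithelial=0, stroma=10)) == 0.0

    def test_zero_stroma_is_undefined(self):
        assert np.isnan(area_ratio(_mask(epithelial=5, stroma=0)))

    def test_matches_pixel_tally(self, rng):
        for _ in range(30):
            mask = rng.integers(0, 3, (16, 16)).astype(np.uint8)
            n_e = sum(1 for v in mask.ravel() if v == EPITHELIAL)
            n_s = sum(1 for v in mask.ravel() if v == STROMA)
            got = area_ratio(mask)
            if n_s == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(n_e / n_s)

    def test_outer_region_irrelevant(self, rng):
        mask = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        mask[0, 0] = STROMA  # guarantee definedness
        grown = mask.copy()
        grown[mask == OUTER] = OUTER  # no-op; now pad with extra outer
        padded = np.pad(mask, 8, constant_values=OUTER)
        assert area_ratio(padded) == pytest.approx(area_ratio(mask))


class TestMeanSHGInStroma:
    def _image(self, shg8):
        shg8 = np.asarray(shg8, dtype=np.uint8)
        return MPMImage(shg=shg8, af=np.zeros_like(shg8), bit_depth=8)

    def test_constant_stroma(self):
        mask = np.full((4, 4), STROMA, dtype=np.uint8)
        assert mean_shg_in_stroma(self._image(np.full((4, 4), 10)), mask) == 10.0

    def test_two_pixel_average(self):
        mask = np.full((2, 2), OUTER, dtype=np.uint8)
        mask[0, 0] = mask[0, 1] = STROMA
        shg = np.zeros((2, 2), dtype=np.uint8)
        shg[0, 1] = 255
        assert mean_shg_in_stroma(self._image(shg), mask) == pytest.approx(127.5)

    def test_measured_on_8bit_conversion(self):
        # 12-bit input must be floor(v/16)-converted before averaging
        mask = np.full((2, 2), STROMA, dtype=np.uint8)
        img12 = MPMImage(shg=np.full((2, 2), 4095, dtype=np.uint16),
                         af=np.zeros((2, 2), dtype=np.uint16), bit_depth=12)
        assert mean_shg_in_stroma(img12, mask) == 255.0

    def test_matches_masked_mean_oracle(self, rng):
        for _ in range(30):
            mask = rng.integers(0, 3, (12, 12)).astype(np.uint8)
            shg = rng.integers(0, 256, (12, 12)).astype(np.uint8)
            vals = [int(s) for s, m in zip(shg.ravel(), mask.ravel()) if m == STROMA]
            got = mean_shg_in_stroma(self._image(shg), mask)
            if not vals:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(sum(vals) / len(vals))

    def test_outer_intensity_irrelevant(self, rng):
        mask = rng.integers(0, 3, (12, 12)).astype(np.uint8)
        mask[0, 0] = STROMA
        shg = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        altered = shg.copy()
        altered[mask == OUTER] = 255
        assert mean_shg_in_stroma(self._image(shg), mask) == mean_shg_in_stroma(
            self._image(altered), mask
        )


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [3, 1, 2])
        assert d == 0.0 and p == 1.0

    def test_fully_separated(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_exact_p_matches_full_enumeration(self, rng):
        for _ in range(20):
            x = rng.integers(0, 8, size=5).tolist()
            y = rng.integers(0, 8, size=5).tolist()
            d, p = ks_two_sample(x, y, method="exact")
            assert d == pytest.approx(ks_statistic_loop(x, y))
            assert p == pytest.approx(ks_exact_p_enumeration(x, y))

    def test_statistic_matches_loop_oracle_with_ties(self, rng):
        for _ in range(100):
            nx, ny = rng.integers(3, 30, size=2)
            x = rng.integers(0, 10, size=nx)
            y = rng.integers(0, 10, size=ny)
            d, _ = ks_two_sample(x, y, method="asymp")
            assert d == pytest.approx(ks_statistic_loop(x, y))

    def test_symmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=9)
        assert ks_two_sample(x, y) == ks_two_sample(y, x)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyInputError):
            ks_two_sample([], [1.0])

    def test_null_calibration(self):
        # type-I error of p<0.05 under the null, n=30 per group
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = ks_two_sample(x, y, method="asymp")
            hits += p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 6), min_size=2, max_size=6),
    st.lists(st.integers(0, 6), min_size=2, max_size=6),
)
def test_ks_properties(x, y):
    d, p = ks_two_sample(x, y)
    assert 0.0 <= d <= 1.0 and 0.0 < p <= 1.0
    d2, p2 = ks_two_sample(y, x)
    assert d == d2 and p == p2


class TestScoreDataset:
    def test_ground_truth_scores(self, tiny_cohort):
        records, stats = score_dataset(tiny_cohort, "ground_truth")
        assert len(records) == len(tiny_cohort)
        assert all(r.defined for r in records)
        assert set(stats.n) == {"FA", "PT"}

    def test_predicted_equals_truth_for_perfect_masks(self, tiny_cohort):
        truth_masks = {
            iid: tiny_cohort.masks[iid] for iid in tiny_cohort.frame["image_id"]
        }
        gt_records, _ = score_dataset(tiny_cohort, "ground_truth")
        pr_records, _ = score_dataset(tiny_cohort, "predicted", predicted_masks=truth_masks)
        for a, b in zip(gt_records, pr_records):
            assert a.area_ratio == b.area_ratio
            assert a.shg_stroma_mean == b.shg_stroma_mean

    def test_missing_mask_skipped_with_warning(self, tiny_cohort, caplog):
        partial = {
            iid: tiny_cohort.masks[iid]
            for iid in tiny_cohort.frame["image_id"][1:]
        }
        import logging

        with caplog.at_level(logging.WARNING):
            records, _ = score_dataset(tiny_cohort, "predicted", predicted_masks=partial)
        assert len(records) == len(tiny_cohort) - 1
        assert any("skipped" in m for m in caplog.messages)

    def test_identical_images_have_zero_sd(self, tiny_cohort):
        # duplicate one image under several ids
        import pandas as pd
        from phylloseg import DatasetManifest

        iid = tiny_cohort.frame["image_id"].iloc[0]
        rows = []
        for j, lesion in enumerate(["FA", "FA", "PT", "PT"]):
            rows.append(dict(image_id=f"d{j}", patient_id=f"p{j}", lesion=lesion,
                             image_path="", mask_path="", seed=0))
        man = DatasetManifest(
            frame=pd.DataFrame(rows),
            images={f"d{j}": tiny_cohort.images[iid] for j in range(4)},
            masks={f"d{j}": tiny_cohort.masks[iid] for j in range(4)},
        )
        _, stats = score_dataset(man, "ground_truth")
        assert stats.area_ratio_sd["FA"] == 0.0 and stats.shg_sd["PT"] == 0.0
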