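"""Generator contracts: mask partitioning, fraction calibration, rendering
noise model, cohort bookkeeping, reproducibility, and per-patient
correlation."""

import numpy as np
import pytest

from phylloseg import (
    OUTER,
    STROMA,
    EPITHELIAL,
    CohortSpec,
    MorphologyParams,
    OpticsParams,
    fa_morphology,
    pt_morphology,
    generate_tissue_mask,
    render_mpm_image,
    generate_cohort,
)
from phylloseg.errors import InvalidParameterError
from phylloseg.scoring import area_ratio

from oracles import icc_oneway


class TestGenerateTissueMask:
    def test_degenerate_fractions(self):
        morph = MorphologyParams(
            epithelial_fraction_mean=0.0, epithelial_fraction_sd=0.0, tissue_coverage=1.0
        )
        mask = generate_tissue_mask(morph, frame_size=64, rng_seed=0)
        assert (mask != EPITHELIAL).all() and (mask != OUTER).all()

    def test_zero_coverage_is_all_outer(self):
        mask = generate_tissue_mask(
            MorphologyParams(tissue_coverage=0.0), frame_size=64, rng_seed=0
        )
        assert (mask == OUTER).all()

    def test_mask_partitions_frame(self):
        for seed, morph in enumerate([fa_morphology(), pt_morphology()]):
            mask = generate_tissue_mask(morph, frame_size=128, rng_seed=seed)
            counts = np.bincount(mask.ravel(), minlength=3)
            assert counts.sum() == 128 * 128
            assert set(np.unique(mask)) <= {OUTER, STROMA, EPITHELIAL}

    def test_epithelium_strictly_inside_tissue(self):
        mask = generate_tissue_mask(fa_morphology(), frame_size=128, rng_seed=3)
        epi = np.argwhere(mask == EPITHELIAL)
        # no epithelial pixel touches the Outer region in 4-neighbourhood
        padded = np.pad(mask, 1, constant_values=OUTER)
        for r, c in epi[:: max(len(epi) // 200, 1)]:
            neigh = padded[r : r + 3, c : c + 3]
            assert (neigh != OUTER).all()

    def test_fraction_calibration_monte_carlo(self):
        # empirical mean of epithelial/(epithelial+stromal) over many draws
        # stays within +/-0.03 of the configured 0.3 target
        morph = fa_morphology()
        fracs = []
        for seed in range(300):
            mask = generate_tissue_mask(morph, frame_size=128, rng_seed=seed)
            fracs.append(
                (mask == EPITHELIAL).sum() / max((mask != OUTER).sum(), 1)
            )
        assert abs(np.mean(fracs) - morph.epithelial_fraction_mean) < 0.03

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            MorphologyParams(epithelial_fraction_mean=1.2)
        with pytest.raises(InvalidParameterError):
            MorphologyParams(duct_eccentricity=1.0)
        with pytest.raises(InvalidParameterError):
            MorphologyParams(duct_count_mean=0.0)


class TestRenderMPMImage:
    def test_noise_free_uniform_stroma_is_constant(self):
        optics = OpticsParams(frame_size=32, shot_noise=False, read_noise_sd=0.0)
        mask = np.full((32, 32), STROMA, dtype=np.uint8)
        img = render_mpm_image(mask, optics, rng_seed=0)
        assert (img.shg == int(optics.shg_stroma_mean)).all()
        assert (img.af == int(optics.af_stroma_mean)).all()

    def test_same_seed_bit_identical(self):
        optics = OpticsParams(frame_size=32)
        mask = generate_tissue_mask(fa_morphology(), 32, rng_seed=1)
        a = render_mpm_image(mask, optics, rng_seed=9)
        b = render_mpm_image(mask, optics, rng_seed=9)
        assert (a.shg == b.shg).all() and (a.af == b.af).all()

    def test_noisy_class_means_match_configuration(self):
        # per-class means over 100 renders within 1% of configured values
        optics = OpticsParams(frame_size=64)
        mask = generate_tissue_mask(fa_morphology(), 64, rng_seed=2)
        sums = {"shg_s": 0.0, "shg_e": 0.0, "af_s": 0.0, "af_e": 0.0}
        for seed in range(100):
            img = render_mpm_image(mask, optics, rng_seed=seed)
            sums["shg_s"] += img.shg[mask == STROMA].mean()
            sums["shg_e"] += img.shg[mask == EPITHELIAL].mean()
            sums["af_s"] += img.af[mask == STROMA].mean()
            sums["af_e"] += img.af[mask == EPITHELIAL].mean()
        assert sums["shg_s"] / 100 == pytest.approx(optics.shg_stroma_mean, rel=0.01)
        assert sums["shg_e"] / 100 == pytest.approx(optics.shg_epithelial_mean, rel=0.01)
        assert sums["af_s"] / 100 == pytest.approx(optics.af_stroma_mean, rel=0.01)
        assert sums["af_e"] / 100 == pytest.approx(optics.af_epithelial_mean, rel=0.01)

    def test_shape_mismatch_raises(self):
        with pytest.raises(InvalidParameterError):
            render_mpm_image(np.zeros((16, 16), dtype=np.uint8), OpticsParams(frame_size=32))


class TestGenerateCohort:
    def test_default_design_counts(self, cohort128):
        by_lesion = cohort128.frame.groupby("lesion").size()
        assert by_lesion["FA"] == 33 and by_lesion["PT"] == 43
        assert len(cohort128) == 76
        per_patient = cohort128.frame.groupby("patient_id").size()
        assert len(per_patient) == 10
        assert per_patient.between(6, 12).all()

    def test_minimal_spec(self):
        spec = CohortSpec(
            n_patients_per_class=1,
            regions_per_patient_range=(2, 2),
            target_totals={"FA": 2, "PT": 2},
            seed=0,
        )
        man = generate_cohort(spec, frame_size=32)
        assert len(man) == 4
        assert man.frame["patient_id"].nunique() == 2

    def test_infeasible_totals_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(n_patients_per_class=5, regions_per_patient_range=(6, 12),
                       target_totals={"FA": 5, "PT": 43})
        with pytest.raises(InvalidParameterError):
            CohortSpec(regions_per_patient_range=(0, 12))

    def test_reproducible_bit_identical(self):
        spec = CohortSpec(
            n_patients_per_class=2,
            regions_per_patient_range=(2, 3),
            target_totals={"FA": 5, "PT": 5},
            seed=77,
        )
        a = generate_cohort(spec, frame_size=32)
        b = generate_cohort(spec, frame_size=32)
        assert a.frame.equals(b.frame)
        for iid in a.frame["image_id"]:
            assert (a.masks[iid] == b.masks[iid]).all()
            assert (a.images[iid].shg == b.images[iid].shg).all()
            assert (a.images[iid].af == b.images[iid].af).all()

    def test_files_round_trip(self, tmp_path):
        spec = CohortSpec(
            n_patients_per_class=1, regions_per_patient_range=(2, 2),
            target_totals={"FA": 2, "PT": 2}, seed=3,
        )
        in_mem = generate_cohort(spec, frame_size=32)
        on_disk = generate_cohort(spec, frame_size=32, out_dir=tmp_path)
        from phylloseg import DatasetManifest

        loaded = DatasetManifest.load_csv(tmp_path / "manifest.csv")
        for iid in in_mem.frame["image_id"]:
            assert (loaded.load_mask(iid) == in_mem.masks[iid]).all()
            assert (loaded.load_image(iid).shg == in_mem.images[iid].shg).all()

    def test_directional_contrasts(self, cohort128):
        # the two qualitative group contrasts the analysis relies on
        from phylloseg.scoring import mean_shg_in_stroma

        ratios = {"FA": [], "PT": []}
        shg = {"FA": [], "PT": []}
        for _, row in cohort128.frame.iterrows():
            mask = cohort128.load_mask(row["image_id"])
            ratios[row["lesion"]].append(area_ratio(mask))
            shg[row["lesion"]].append(
                mean_shg_in_stroma(cohort128.load_image(row["image_id"]), mask)
            )
        assert np.mean(ratios["PT"]) > np.mean(ratios["FA"])
        assert np.mean(shg["FA"]) > np.mean(shg["PT"])

    def test_within_patient_correlation_positive(self):
        # per-patient random effects must induce ICC > 0 for the area ratio
        iccs = []
        for seed in range(30):
            spec = CohortSpec(
                n_patients_per_class=5,
                regions_per_patient_range=(4, 4),
                target_totals={"FA": 20, "PT": 20},
                seed=1000 + seed,
            )
            man = generate_cohort(spec, frame_size=64)
            fa = man.frame[man.frame["lesion"] == "FA"]
            groups = [
                np.array([area_ratio(man.masks[i]) for i in grp["image_id"]])
                for _, grp in fa.groupby("patient_id")
            ]
            iccs.append(icc_oneway(groups))
        assert np.mean(iccs) > 0.0
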