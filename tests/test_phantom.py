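"""Cohort sampling and phantom rendering: distributions, geometry, I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from abequant import (
    PhantomConfig,
    SubjectRecord,
    generate_cohort,
    render_subject,
    sample_cohort,
    write_dataset,
)
from abequant.errors import ConfigurationError, IntegrityError, RenderingError
from abequant.phantom import (
    GP,
    STN,
    WM,
    MIN_ROI_PIXELS,
    read_cohort_table,
    read_subject_stack,
    records_to_frame,
    roi_slice_indices,
    slice_geometry,
)


def _make_record(gp=1.39, stn=1.47, group="ABE"):
    return SubjectRecord(
        subject_id="T0001", group=group, sex="M", age_days=9.0, weight_kg=3.2,
        gestational_age_weeks=38.5, tsb_umol_per_l=350.0, albumin_g_per_l=38.0,
        bind_score=2, true_gp_ratio=gp, true_stn_ratio=stn,
    )


class TestSampleCohort:
    def test_default_study_cohort_counts(self):
        records = sample_cohort(PhantomConfig())
        assert len(records) == 79
        assert sum(r.group == "ABE" for r in records) == 47
        assert sum(r.group == "non-ABE" for r in records) == 32

    @pytest.mark.parametrize("kwargs", [
        {"n_pos": 0}, {"n_neg": 0}, {"wm_mean": -1.0}, {"noise_cv": -0.1},
        {"wm_mean": float("nan")},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            PhantomConfig(**kwargs)

    def test_negative_ratio_sd_rejected(self):
        cfg = PhantomConfig().to_dict()
        cfg["ratio_params"]["ABE"]["GP"] = [1.39, -0.06]
        with pytest.raises(ConfigurationError):
            PhantomConfig.from_dict(cfg)

    def test_replicate_grand_mean_matches_configured_distribution(self):
        """Over many replicate cohorts the ABE true GP ratio averages to 1.39."""
        rng = np.random.default_rng(7)
        cfg = PhantomConfig()
        vals = []
        for _ in range(500):
            vals.extend(r.true_gp_ratio for r in sample_cohort(cfg, rng) if r.group == "ABE")
        assert abs(np.mean(vals) - 1.39) < 0.005

    def test_covariates_respect_physiologic_clamps(self):
        rng = np.random.default_rng(1)
        for rec in sample_cohort(PhantomConfig(), rng):
            assert 1.0 <= rec.age_days <= 18.0
            assert rec.true_gp_ratio > 0 and rec.true_stn_ratio > 0
            assert rec.sex in ("M", "F")
            assert (rec.bind_score >= 1) == (rec.group == "ABE")

    def test_seed_reproducibility(self):
        a = sample_cohort(PhantomConfig(seed=5))
        b = sample_cohort(PhantomConfig(seed=5))
        assert a == b

    def test_group_label_exchangeability(self):
        """Swapping the ratio parameters between groups and relabeling gives a
        statistically identical dataset (compared on summary moments)."""
        cfg = PhantomConfig()
        swapped = cfg.to_dict()
        swapped["ratio_params"] = {
            "ABE": cfg.ratio_params["non-ABE"],
            "non-ABE": cfg.ratio_params["ABE"],
        }
        cfg_swapped = PhantomConfig.from_dict(swapped)
        rng_a, rng_b = np.random.default_rng(11), np.random.default_rng(12)
        a = [r.true_gp_ratio for _ in range(200)
             for r in sample_cohort(cfg, rng_a) if r.group == "ABE"]
        b = [r.true_gp_ratio for _ in range(200)
             for r in sample_cohort(cfg_swapped, rng_b) if r.group == "non-ABE"]
        # each mean has SE ~ 0.06/sqrt(200*47) ~ 6e-4
        assert abs(np.mean(a) - np.mean(b)) < 0.004
        assert abs(np.std(a) - np.std(b)) < 0.004


class TestRenderSubject:
    def test_noiseless_ratio_identity(self):
        cfg = PhantomConfig(noise_cv=0.0, n_slices=3)
        stack = render_subject(_make_record(gp=1.39), cfg)
        slc = stack[1]
        gp_mean = slc.intensity[slc.mask == GP].mean()
        wm_mean = slc.intensity[slc.mask == WM].mean()
        assert gp_mean / wm_mean == pytest.approx(1.39, abs=1e-12)

    def test_default_stack_has_18_slices(self):
        stack = render_subject(_make_record(), PhantomConfig())
        assert len(stack) == 18
        assert [s.slice_index for s in stack] == list(range(18))

    def test_roi_codes_only_on_central_slices(self):
        cfg = PhantomConfig(noise_cv=0.0)
        stack = render_subject(_make_record(), cfg)
        roi_idx = set(roi_slice_indices(cfg.n_slices))
        for s in stack:
            codes = set(np.unique(s.mask))
            if s.slice_index in roi_idx:
                assert codes == {0, WM, GP, STN}
                for code in (WM, GP, STN):
                    assert (s.mask == code).sum() >= MIN_ROI_PIXELS
            else:
                assert codes == {0}

    def test_too_small_grid_rejected(self):
        with pytest.raises(RenderingError):
            slice_geometry((32, 32))

    def test_noise_scales_with_regional_mean(self):
        cfg = PhantomConfig(noise_cv=0.10, n_slices=3, seed=0)
        stack = render_subject(_make_record(gp=1.5), cfg, np.random.default_rng(0))
        slc = stack[1]
        gp_sd = slc.intensity[slc.mask == GP].std()
        wm_sd = slc.intensity[slc.mask == WM].std()
        assert gp_sd == pytest.approx(0.10 * cfg.wm_mean * 1.5, rel=0.25)
        assert wm_sd == pytest.approx(0.10 * cfg.wm_mean, rel=0.25)

    def test_extracted_ratio_nearly_unbiased_under_noise(self):
        """Ratio of ROI means is second-order-biased in the noise level."""
        cfg = PhantomConfig(noise_cv=0.02, n_slices=3, slice_shape=(96, 96))
        rng = np.random.default_rng(123)
        ratios = []
        for _ in range(200):
            stack = render_subject(_make_record(gp=1.39), cfg, rng)
            slc = stack[1]
            ratios.append(
                slc.intensity[slc.mask == GP].mean() / slc.intensity[slc.mask == WM].mean()
            )
        assert abs(np.mean(ratios) - 1.39) < 0.01


class TestWriteDataset:
    def test_file_counts_and_roundtrip(self, small_dataset_dir, small_cohort):
        records, stacks = small_cohort
        imgs = list(small_dataset_dir.glob("*_t1.nii.gz"))
        msks = list(small_dataset_dir.glob("*_mask.nii.gz"))
        assert len(imgs) == len(records) and len(msks) == len(records)
        table = read_cohort_table(small_dataset_dir)
        assert len(table) == len(records)
        sid = records[0].subject_id
        back = read_subject_stack(small_dataset_dir, sid)
        orig = sorted(stacks[sid], key=lambda s: s.slice_index)
        for a, b in zip(orig, back):
            assert np.array_equal(a.intensity.astype(np.float32), b.intensity)
            assert np.array_equal(a.mask, b.mask)

    def test_manifest_seed_replay_reproduces_cohort_table(self, small_dataset_dir):
        import json

        manifest = json.loads((small_dataset_dir / "manifest.json").read_text())
        cfg = PhantomConfig.from_dict(manifest["config"])
        assert cfg.seed == manifest["seed"]
        records, _ = generate_cohort(cfg)
        replay = records_to_frame(records)
        on_disk = read_cohort_table(small_dataset_dir)
        pd.testing.assert_frame_equal(
            replay.reset_index(drop=True), on_disk, check_dtype=False
        )

    def test_subject_id_mismatch_rejected(self, tmp_path, small_cohort, small_config):
        records, stacks = small_cohort
        with pytest.raises(IntegrityError):
            write_dataset({k: v for k, v in list(stacks.items())[:-1]},
                          records, tmp_path, small_config)

    def test_voxel_identical_regeneration(self, small_config):
        _, stacks_a = generate_cohort(small_config)
        _, stacks_b = generate_cohort(dataclasses.replace(small_config))
        sid = next(iter(stacks_a))
        for a, b in zip(stacks_a[sid], stacks_b[sid]):
            assert np.array_equal(a.intensity, b.intensity)
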