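import dataclasses

import numpy as np
import pytest

from dsoct import (
    CriteriaConfig,
    FitConfig,
    MModeStack,
    PhantomSpec,
    ROIResult,
    SurfaceNotFoundError,
    analyze_stack,
    apply_criteria,
    detect_surface,
    get_preset,
    make_phantom_stack,
    sample_summary,
    segment_rois,
    solvent_reference_diffusivities,
)


class TestDetectSurface:
    def test_phantom_surface_found_exactly(self, optics_62k5):
        for surf in (12, 40):
            spec = PhantomSpec.uniform(
                2.0, 2000.0, 64, surface_index=surf, noise_level=0.05,
                n_times=2000, seed=surf,
            )
            stack = make_phantom_stack(spec, optics_62k5)
            assert detect_surface(stack) == surf

    def test_all_noise_stack_raises(self, optics_62k5):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((2000, 64)) + 1j * rng.standard_normal((2000, 64))
        stack = MModeStack(s_hh=0.05 * noise, s_hv=0.05 * noise, optics=optics_62k5)
        with pytest.raises(SurfaceNotFoundError):
            detect_surface(stack)

    def test_surface_at_pixel_zero(self, optics_62k5):
        # strong specular at the very top: robust noise statistics over the
        # top pixels still single it out
        spec = PhantomSpec.uniform(
            2.0, 2000.0, 64, surface_index=0, noise_level=0.05, n_times=2000, seed=1
        )
        stack = make_phantom_stack(spec, optics_62k5)
        assert detect_surface(stack) == 0

    def test_shallow_stack_rejected(self, optics_62k5):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((100, 16)) + 0j
        with pytest.raises(ValueError):
            detect_surface(MModeStack(s_hh=sig, s_hv=sig, optics=optics_62k5))

    def test_error_within_one_pixel_across_seeds(self, optics_62k5):
        errs = []
        for seed in range(30):
            spec = PhantomSpec.uniform(
                2.0, 2000.0, 64, surface_index=20, noise_level=0.1,
                n_times=1000, seed=seed,
            )
            stack = make_phantom_stack(spec, optics_62k5)
            errs.append(abs(detect_surface(stack) - 20))
        assert max(errs) <= 1


class TestSegmentRois:
    def test_stationary_geometry(self):
        cfg = CriteriaConfig(surface_offset_px=15, roi_height_px=20)
        assert segment_rois(40, 115, cfg) == [(55, 75), (75, 95), (95, 115)]

    def test_culture_geometry(self):
        cfg = CriteriaConfig(surface_offset_px=5, roi_height_px=3)
        assert segment_rois(40, 51, cfg) == [(45, 48), (48, 51)]

    def test_no_room_gives_empty_list(self):
        cfg = CriteriaConfig(surface_offset_px=15, roi_height_px=20)
        assert segment_rois(49, 64, cfg) == []

    def test_small_final_partial_window_dropped(self):
        cfg = CriteriaConfig(surface_offset_px=0, roi_height_px=20)
        # remaining 9 px < height/2 -> dropped; 10 px -> kept
        assert segment_rois(0, 49, cfg) == [(0, 20), (20, 40)]
        assert segment_rois(0, 50, cfg) == [(0, 20), (20, 40), (40, 50)]


def nominal_roi(**overrides):
    base = dict(
        depth_range=(25, 45),
        tau_iso_s=3e-4,
        tau_hv_s=6e-5,
        dt_um2_s=2.0,
        dr_rad2_s=2500.0,
        r2_iso=0.98,
        r2_hv=0.99,
        mean_hh_power=1.0,
        flags={"surface": True, "snr": True},
    )
    base.update(overrides)
    return ROIResult(**base)


class TestApplyCriteria:
    BOUNDS = (3.2e-5, 4.8e-2)

    def test_all_nominal_passes(self):
        r = apply_criteria(nominal_roi(), CriteriaConfig(), tau_bounds_s=self.BOUNDS)
        assert r.valid_dt and r.valid_dr

    def test_low_anisotropy_fails_both(self):
        r = nominal_roi(tau_iso_s=7.2e-5, tau_hv_s=6e-5)  # ratio 1.2 < 1.5
        r = apply_criteria(r, CriteriaConfig(), tau_bounds_s=self.BOUNDS)
        assert not r.flags["anisotropy"]
        assert not r.valid_dt and not r.valid_dr

    def test_r2_gates_are_per_channel(self):
        cfg_peo, _ = get_preset("stationary_peo")
        r = apply_criteria(
            nominal_roi(r2_iso=0.85, r2_hv=0.95), cfg_peo, tau_bounds_s=self.BOUNDS
        )
        assert not r.valid_dt and r.valid_dr

    def test_dynamic_range_gates_are_per_channel(self):
        r = apply_criteria(
            nominal_roi(tau_hv_s=1e-5), CriteriaConfig(), tau_bounds_s=self.BOUNDS
        )
        assert not r.flags["hv_range"] and r.flags["iso_range"]
        assert r.valid_dt and not r.valid_dr

    def test_culture_mode_skips_r2_and_outliers(self):
        cfg, _ = get_preset("culture")
        r = apply_criteria(
            nominal_roi(r2_iso=0.2, r2_hv=0.1), cfg, tau_bounds_s=self.BOUNDS
        )
        assert r.valid_dt and r.valid_dr

    def test_outlier_is_flag_not_exclusion(self):
        context = [nominal_roi(dt_um2_s=2.0 + 0.01 * i) for i in range(10)]
        extreme = nominal_roi(dt_um2_s=50.0)
        r = apply_criteria(
            extreme, CriteriaConfig(), sample_context=context, tau_bounds_s=self.BOUNDS
        )
        assert r.flags["outlier_dt"]
        assert r.valid_dt  # flagged for review, still valid

    def test_idempotent(self):
        cfg = CriteriaConfig()
        r1 = apply_criteria(nominal_roi(), cfg, tau_bounds_s=self.BOUNDS)
        snapshot = (dict(r1.flags), r1.valid_dt, r1.valid_dr)
        r2 = apply_criteria(r1, cfg, tau_bounds_s=self.BOUNDS)
        assert (dict(r2.flags), r2.valid_dt, r2.valid_dr) == snapshot

    @pytest.mark.parametrize(
        "field, factor",
        [("anisotropy_min", 2.0), ("r2_threshold", 1.05), ("tau_min_factor", 4.0)],
    )
    def test_tightening_thresholds_is_monotone(self, field, factor):
        cfg = CriteriaConfig()
        tight = dataclasses.replace(cfg, **{field: getattr(cfg, field) * factor})
        rois = [
            nominal_roi(),
            nominal_roi(tau_iso_s=1e-4, tau_hv_s=6.5e-5),
            nominal_roi(r2_iso=0.91, r2_hv=0.92),
            nominal_roi(tau_hv_s=3.3e-5),
        ]
        def copy(r):
            return ROIResult(
                **{f.name: getattr(r, f.name) for f in dataclasses.fields(ROIResult)}
            )

        for r in rois:
            loose = apply_criteria(copy(r), cfg, tau_bounds_s=self.BOUNDS)
            bounds = self.BOUNDS
            if field == "tau_min_factor":
                bounds = (bounds[0] * factor, bounds[1])
            strict = apply_criteria(copy(r), tight, tau_bounds_s=bounds)
            # tightening can only remove validity, never grant it
            if strict.valid_dt:
                assert loose.valid_dt
            if strict.valid_dr:
                assert loose.valid_dr


class TestAnalyzeStack:
    def test_uniform_phantom_recovery(self, uniform_stack):
        cfg, fit = get_preset("stationary_mucus")
        results = analyze_stack(uniform_stack, cfg, fit)
        assert results, "expected at least one ROI"
        assert all(r.valid_dt for r in results)
        for r in results:
            assert r.dt_um2_s == pytest.approx(2.0, rel=0.10)

    def test_too_fast_rotation_invalidates_dr_only(self, optics_62k5, batch_68x19):
        # solvent-like rotation at 62.5 kHz decays below the sampling floor:
        # DR is rejected by the dynamic-range rule while DT survives
        dt_true, dr_true = solvent_reference_diffusivities(batch_68x19)
        spec = PhantomSpec.uniform(
            8.5, dr_true, 64, surface_index=10, noise_level=0.05,
            n_times=20_000, seed=21,
        )
        stack = make_phantom_stack(spec, optics_62k5)
        cfg, fit = get_preset("stationary_mucus")
        results = analyze_stack(stack, cfg, fit)
        assert results
        assert all(r.valid_dt for r in results)
        assert not any(r.valid_dr for r in results)

    def test_no_room_below_surface_gives_empty_results(self, optics_62k5):
        spec = PhantomSpec.uniform(
            2.0, 2000.0, 64, surface_index=55, noise_level=0.05,
            n_times=2000, seed=2,
        )
        stack = make_phantom_stack(spec, optics_62k5)
        cfg, fit = get_preset("stationary_mucus")
        assert analyze_stack(stack, cfg, fit) == []

    def test_deterministic(self, uniform_stack):
        cfg, fit = get_preset("stationary_mucus")
        a = analyze_stack(uniform_stack, cfg, fit)
        b = analyze_stack(uniform_stack, cfg, fit)
        assert [r.to_record() for r in a] == [r.to_record() for r in b]


class TestSampleSummary:
    def _rois(self, values, valid=True):
        return [
            nominal_roi(dt_um2_s=v, dr_rad2_s=1000 * v) if valid else nominal_roi(dt_um2_s=v)
            for v in values
        ]

    def test_constant_values_give_zero_cv(self):
        rois = [apply_criteria(r, CriteriaConfig(), tau_bounds_s=(1e-5, 1e-1))
                for r in self._rois([2.0, 2.0, 2.0])]
        s = sample_summary(rois)
        assert s["dt"]["cv_percent"] == pytest.approx(0.0)

    def test_sample_std_convention(self):
        rois = [apply_criteria(r, CriteriaConfig(), tau_bounds_s=(1e-5, 1e-1))
                for r in self._rois([1.0, 2.0, 3.0])]
        s = sample_summary(rois)
        assert s["dt"]["mean"] == pytest.approx(2.0)
        assert s["dt"]["std"] == pytest.approx(1.0)  # ddof=1
        assert s["dt"]["cv_percent"] == pytest.approx(50.0)

    def test_single_valid_roi_is_undefined(self):
        rois = [apply_criteria(r, CriteriaConfig(), tau_bounds_s=(1e-5, 1e-1))
                for r in self._rois([2.0])]
        assert sample_summary(rois)["dt"] is None


class TestPresets:
    def test_preset_constants(self):
        peo, _ = get_preset("stationary_peo")
        assert (peo.surface_offset_px, peo.roi_height_px) == (15, 20)
        assert peo.r2_threshold == 0.88
        mucus, _ = get_preset("stationary_mucus")
        assert mucus.r2_threshold == 0.90
        culture, fit = get_preset("culture")
        assert (culture.surface_offset_px, culture.roi_height_px) == (5, 3)
        assert culture.culture_mode
        assert fit.iso_rule.value == "dynamic"
        for cfg in (peo, mucus, culture):
            assert cfg.anisotropy_min == 1.5

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            get_preset("nope")
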