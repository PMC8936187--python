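import numpy as np
import pandas as pd
import pytest

from octavd import (
    CohortEffectSpec,
    NoiseParams,
    VesselParams,
    generate_vessel_mask,
    make_phantom,
    render_octa,
    simulate_cohort,
    vessel_density,
)
from octavd.phantom import PhantomError


class TestVesselMask:
    def test_fraction_lands_in_stopping_band(self):
        mask = generate_vessel_mask(VesselParams(target_fraction=0.25), seed=3)
        frac = mask.mean()
        assert 0.25 <= frac <= 0.27
        assert vessel_density(mask) == pytest.approx(100.0 * frac)

    def test_deterministic_under_seed(self):
        p = VesselParams()
        a = generate_vessel_mask(p, seed=42)
        b = generate_vessel_mask(p, seed=42)
        assert np.array_equal(a, b)
        c = generate_vessel_mask(p, seed=43)
        assert not np.array_equal(a, c)

    def test_higher_target_gives_denser_mask(self):
        hi = generate_vessel_mask(VesselParams(target_fraction=0.25), seed=9)
        lo = generate_vessel_mask(VesselParams(target_fraction=0.10), seed=9)
        assert hi.sum() > lo.sum()
        assert 0.10 <= lo.mean() <= 0.12

    def test_unreachable_target_reports_achieved_fraction(self):
        params = VesselParams(
            target_fraction=0.5, n_seeds=1, branch_prob=0.0, width_range=(1.0, 1.0)
        )
        with pytest.raises(PhantomError, match="achieved fraction"):
            generate_vessel_mask(params, seed=1, max_strokes=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"target_fraction": 0.0},
            {"target_fraction": 0.7},
            {"width_range": (0.5, 3.0)},
            {"image_size": 32},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_vessel_mask(VesselParams(**kwargs), seed=0)


class TestRender:
    def test_noise_free_limit_is_two_level(self, truth_mask):
        nz = NoiseParams(speckle_shape=np.inf, stripe_amplitude=0.0, blur_sigma=0.0)
        img = render_octa(truth_mask, nz, seed=0)
        assert np.array_equal(
            img, np.where(truth_mask, nz.vessel_level, nz.background_level)
        )

    def test_vessels_brighter_than_background(self, truth_mask, noisy_image):
        assert noisy_image[truth_mask].mean() > noisy_image[~truth_mask].mean()

    def test_stripes_concentrate_on_vertical_frequency_axis(self, truth_mask):
        base = NoiseParams(stripe_amplitude=0.0)
        striped = NoiseParams(stripe_amplitude=0.4, stripe_rows_fraction=0.1)
        img0 = render_octa(truth_mask, base, seed=5)
        img1 = render_octa(truth_mask, striped, seed=5)
        # horizontal full-width stripes live in the fx=0 spectral column
        ax0 = np.abs(np.fft.fft2(img0)[:, 0]) ** 2
        ax1 = np.abs(np.fft.fft2(img1)[:, 0]) ** 2
        assert ax1[1:].sum() > 2.0 * ax0[1:].sum()

    def test_deterministic_under_seed(self, truth_mask):
        a = render_octa(truth_mask, NoiseParams(), seed=8)
        b = render_octa(truth_mask, NoiseParams(), seed=8)
        assert np.array_equal(a, b)

    def test_output_clipped_to_unit_range(self, truth_mask):
        img = render_octa(truth_mask, NoiseParams(stripe_amplitude=0.9), seed=2)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_invalid_levels_rejected(self, truth_mask):
        with pytest.raises(ValueError):
            render_octa(truth_mask, NoiseParams(vessel_level=0.1, background_level=0.5))


class TestScene:
    def test_scene_reproducible_and_consistent(self):
        p = VesselParams(image_size=128, target_fraction=0.2)
        a = make_phantom(p, NoiseParams(), seed=7)
        b = make_phantom(p, NoiseParams(), seed=7)
        assert np.array_equal(a.truth_mask, b.truth_mask)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert a.truth_mask.shape == a.image.pixels.shape
        assert a.truth_vd == pytest.approx(100.0 * a.truth_mask.mean())


class TestCohortSimulation:
    def test_degenerate_sds_reproduce_visit_means_exactly(self):
        spec = CohortEffectSpec(
            between_eye_sd=0.0, measurement_sd=0.0, dropout_per_visit=(0,) * 5
        )
        df = simulate_cohort(spec, seed=0)
        for vi, visit in enumerate(spec.visits):
            imp = df[(df["visit"] == visit) & df["implant"]]["vd"]
            assert np.allclose(imp, spec.implant_mean_vd[vi])
            ctl = df[(df["visit"] == visit) & ~df["implant"]]["vd"]
            assert np.allclose(ctl, spec.control_mean_vd[vi])

    def test_baseline_implant_mean_near_cohort_value(self):
        # stochastic check: sample mean of pre-op implant VD within 3 SE of 25.6
        spec = CohortEffectSpec()
        df = simulate_cohort(spec, seed=12)
        pre = df[(df["visit"] == "pre") & df["implant"]]["vd"]
        assert pre.size == 25
        se = 3.4 / np.sqrt(25)
        assert abs(pre.mean() - 25.6) < 3 * se

    def test_dropout_profile_matches_visit_counts(self):
        df = simulate_cohort(CohortEffectSpec(), seed=1)
        counts = df[df["implant"]].groupby("visit")["eye_id"].nunique()
        assert [counts[v] for v in ("pre", "week1", "month1", "month3", "month6")] == [
            25, 25, 23, 16, 13,
        ]
        # dropout is monotone: an eye absent at a visit stays absent
        eyes_by_visit = [
            set(df[df["visit"] == v]["eye_id"]) for v in CohortEffectSpec().visits
        ]
        for earlier, later in zip(eyes_by_visit, eyes_by_visit[1:]):
            assert later <= earlier

    def test_table_deterministic_under_seed(self):
        a = simulate_cohort(seed=5)
        b = simulate_cohort(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_sector_design_is_valid(self):
        from octavd import assign_controls

        df = simulate_cohort(seed=3)
        for eye, g in df.groupby("eye_id"):
            implant = set(g[g["implant"]]["sector"])
            controls = set(g[~g["implant"]]["sector"])
            assert len(implant) == 1
            assert controls == set(assign_controls(implant.pop()))

    def test_excessive_dropout_rejected(self):
        with pytest.raises(ValueError, match="3 eyes"):
            simulate_cohort(CohortEffectSpec(n_eyes=5, dropout_per_visit=(0, 0, 1, 1, 1)))
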