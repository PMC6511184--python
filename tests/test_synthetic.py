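import numpy as np
import pytest

from octaperf import (
    EffectModel,
    FAZRegion,
    ScanGeometry,
    binarize,
    generate_cohort,
    generate_faz,
    generate_surfaces,
    generate_vessel_network,
    mean_threshold,
    render_angiogram,
)
from octaperf.synthetic import CohortParams

from _harness import null_scp_pvalues


class TestGenerateSurfaces:
    G = ScanGeometry(6.0, 350)

    def test_pit_deepest_at_center_flat_periphery(self):
        s = generate_surfaces(self.G, 80.0, 0.0, 0.0, seed=1)
        ci = self.G.n_px // 2
        # depth increases posteriorly: the pit pushes the ILM deepest centrally
        # (up to the few-um seeded undulation)
        assert s.z_ilm[ci, ci] >= s.z_ilm.max() - 5.0
        assert s.z_ilm[ci, ci] - s.z_ilm[0, 0] > 60.0
        # periphery is flat up to the small seeded undulation
        corner_spread = s.z_ilm[0, 0] - 150.0
        assert abs(corner_spread) < 10.0

    def test_vmt_pull_confined_to_disk(self):
        base = generate_surfaces(self.G, 80.0, 0.0, 0.0, seed=1)
        vmt = generate_surfaces(self.G, 80.0, 60.0, 800.0, seed=1)
        delta = base.z_ilm - vmt.z_ilm  # positive where the ILM was pulled up
        x, y = self.G.pixel_centers_mm()
        cx, cy = self.G.center_mm
        r = np.hypot(x - cx, y - cy)
        assert np.all(delta[r > 0.4] == 0.0)
        assert delta[r <= 0.4].max() > 50.0

    def test_same_seed_bit_identical(self):
        a = generate_surfaces(self.G, 80.0, 60.0, 800.0, seed=5)
        b = generate_surfaces(self.G, 80.0, 60.0, 800.0, seed=5)
        np.testing.assert_array_equal(a.z_ilm, b.z_ilm)
        np.testing.assert_array_equal(a.z_rpe, b.z_rpe)

    def test_minimum_separation_maintained(self):
        s = generate_surfaces(self.G, 100.0, 80.0, 1400.0, seed=2)
        assert np.all(s.z_rpe - s.z_ilm >= 110.0)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError):
            ScanGeometry(3.0, 0)


class TestGenerateVesselNetwork:
    def test_density_target_on_6mm_preset(self):
        g = ScanGeometry.preset(6.0)
        faz = generate_faz(0.103, g, seed=1)
        net = generate_vessel_network(g, 0.43, faz, seed=1)
        outside = ~faz.raster(g)
        assert 0.41 <= net.pixels[outside].mean() <= 0.45

    def test_faz_interior_strictly_avascular(self, small_geometry, small_faz):
        net = generate_vessel_network(small_geometry, 0.43, small_faz, seed=3)
        assert not net.pixels[small_faz.raster(small_geometry)].any()

    def test_faz_covering_whole_scan_errors(self, small_geometry):
        cover = FAZRegion(
            np.array([(-1.0, -1.0), (4.0, -1.0), (4.0, 4.0), (-1.0, 4.0)])
        )
        with pytest.raises(ValueError, match="no area outside FAZ"):
            generate_vessel_network(small_geometry, 0.43, cover, seed=1)

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_target_rejected(self, small_geometry, small_faz, target):
        with pytest.raises(ValueError, match="target_density"):
            generate_vessel_network(small_geometry, target, small_faz, seed=1)

    def test_two_seeds_differ_same_density(self, small_geometry, small_faz):
        outside = ~small_faz.raster(small_geometry)
        a = generate_vessel_network(small_geometry, 0.43, small_faz, seed=1)
        b = generate_vessel_network(small_geometry, 0.43, small_faz, seed=2)
        assert (a.pixels != b.pixels).any()
        assert abs(a.pixels[outside].mean() - 0.43) < 0.02
        assert abs(b.pixels[outside].mean() - 0.43) < 0.02

    def test_determinism(self, small_geometry, small_faz):
        a = generate_vessel_network(small_geometry, 0.3, small_faz, seed=9)
        b = generate_vessel_network(small_geometry, 0.3, small_faz, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_structured_not_iid_noise(self, small_geometry, small_faz):
        # in a branching network nearly every foreground pixel touches
        # another one; for i.i.d. noise at the same density it would not
        net = generate_vessel_network(small_geometry, 0.3, small_faz, seed=4)
        fg = net.pixels
        neighbours = np.zeros_like(fg, dtype=int)
        neighbours[1:, :] += fg[:-1, :]
        neighbours[:-1, :] += fg[1:, :]
        neighbours[:, 1:] += fg[:, :-1]
        neighbours[:, :-1] += fg[:, 1:]
        frac_connected = (neighbours[fg] > 0).mean()
        assert frac_connected > 0.99


class TestRenderAngiogram:
    def test_noiseless_identity(self, small_geometry, small_faz):
        net = generate_vessel_network(small_geometry, 0.4, small_faz, seed=1)
        img = render_angiogram(net, 0.0, 0.0, seed=123)
        assert set(np.unique(img.pixels)) <= {0.0, 255.0}
        recovered = binarize(img, mean_threshold(img))
        np.testing.assert_array_equal(recovered.pixels, net.pixels)

    def test_pipeline_density_within_tolerance_under_blur_noise(
        self, small_geometry, small_faz
    ):
        from octaperf import apply_faz_mask, perfusion_density

        net = generate_vessel_network(small_geometry, 0.43, small_faz, seed=7)
        outside = ~small_faz.raster(small_geometry)
        truth_density = net.pixels[outside].mean()
        img = render_angiogram(net, 1.0, 5.0, seed=7)
        masked = apply_faz_mask(binarize(img, mean_threshold(img)), small_faz)
        assert abs(perfusion_density(masked) - truth_density) < 0.02

    def test_same_seed_identical(self, small_geometry, small_faz):
        net = generate_vessel_network(small_geometry, 0.4, small_faz, seed=1)
        a = render_angiogram(net, 1.0, 5.0, seed=8)
        b = render_angiogram(net, 1.0, 5.0, seed=8)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_negative_params_rejected(self, small_geometry, small_faz):
        net = generate_vessel_network(small_geometry, 0.4, small_faz, seed=1)
        with pytest.raises(ValueError):
            render_angiogram(net, -1.0, 0.0)

    def test_default_noise_within_tolerance_over_20_seeds(
        self, small_geometry, small_faz
    ):
        # ground-truth consistency at the cohort defaults (blur 0.5, noise 5)
        from octaperf import apply_faz_mask, perfusion_density

        defaults = CohortParams()
        outside = ~small_faz.raster(small_geometry)
        for seed in range(20):
            net = generate_vessel_network(small_geometry, 0.43, small_faz, seed=seed)
            truth = net.pixels[outside].mean()
            img = render_angiogram(net, defaults.blur_sigma_px, 5.0, seed=seed + 100)
            masked = apply_faz_mask(binarize(img, mean_threshold(img)), small_faz)
            assert abs(perfusion_density(masked) - truth) < 0.02


class TestGenerateCohort:
    def test_single_eye_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="paired"):
            generate_cohort(1, small_geometry, seed=1)

    def test_ledger_mean_scp_change_near_injected_shift(self, small_geometry):
        cohort = generate_cohort(
            16,
            small_geometry,
            EffectModel(scp_shift=-0.014),
            seed=3,
            include_controls=False,
            plexuses=("SCP",),
        )
        led = cohort.ledger.pivot_table(
            index="eye_id", columns="timepoint", values="true_density"
        )
        change = led["month1"] - led["baseline"]
        se = change.std(ddof=1) / np.sqrt(len(change))
        assert abs(change.mean() - (-0.014)) <= 3 * max(se, 1e-6)

    def test_null_cohorts_mostly_non_significant(self):
        pvals = np.array(null_scp_pvalues(200)[:50])
        assert (pvals >= 0.05).mean() >= 0.90

    def test_determinism(self, small_geometry):
        kw = dict(include_controls=False, plexuses=("SCP",))
        a = generate_cohort(2, small_geometry, seed=5, **kw)
        b = generate_cohort(2, small_geometry, seed=5, **kw)
        assert a.ledger.equals(b.ledger)
        key = ("vmt01", "baseline", "SCP")
        np.testing.assert_array_equal(a.images[key].pixels, b.images[key].pixels)

    def test_controls_age_matched_and_unshifted(self, small_geometry):
        cohort = generate_cohort(
            4, small_geometry, EffectModel(scp_shift=-0.1), seed=2, plexuses=("SCP",)
        )
        led = cohort.ledger
        ctl = led[led["group"] == "control"].pivot_table(
            index="eye_id", columns="timepoint", values="target_density"
        )
        assert np.allclose(ctl["month1"], ctl["baseline"])
        ages_vmt = sorted(v for k, v in cohort.ages.items() if k.startswith("vmt"))
        ages_ctl = sorted(v for k, v in cohort.ages.items() if k.startswith("ctl"))
        assert all(abs(a - b) <= 1 for a, b in zip(ages_vmt, ages_ctl))

    def test_shift_out_of_range_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="leaves"):
            generate_cohort(
                2,
                small_geometry,
                EffectModel(scp_shift=-0.9),
                seed=1,
                include_controls=False,
                plexuses=("SCP",),
            )

    def test_vmt_diameter_eligible(self, small_geometry):
        cohort = generate_cohort(
            3, small_geometry, seed=7, include_controls=False, plexuses=("SCP",)
        )
        vmt_d = cohort.ledger["vmt_adhesion_diameter_um"]
        assert (vmt_d < 1500).all()

    def test_ground_truth_record(self, small_geometry):
        cohort = generate_cohort(
            2, small_geometry, seed=8, include_controls=False, plexuses=("SCP",)
        )
        gt = cohort.ground_truth("vmt01", "baseline")
        faz = cohort.fazes[("vmt01", "baseline")]
        assert gt.faz_area_mm2 == faz.area_mm2
        assert 0 < gt.true_density_scp < 1
        assert np.isnan(gt.true_density_dcp)
        assert gt.vmt_adhesion_diameter_um < 1500
        with pytest.raises(KeyError):
            cohort.ground_truth("nope", "baseline")
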