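import numpy as np
import pytest
from tests_util import build_plain_set

from sialospec import (
    CohortConfig,
    NetConfig,
    WavenumberGrid,
    build_net,
    generate_cohort,
    shapley_attribution,
    summarize_global,
    train,
    zone_features,
)
from sialospec.zone_shap import ZoneScheme, attribute_set, default_zones


class TestZoneSchemes:
    def test_coarse_scheme_has_eight_contiguous_zones(self):
        scheme = default_zones("coarse")
        assert scheme.n_zones == 8
        assert scheme.edges[0] == 650.0 and scheme.edges[-1] == 1800.0
        # contiguity: each zone starts where the previous ends
        assert all(a < b for a, b in zip(scheme.edges, scheme.edges[1:]))

    def test_fine_scheme_splits_carbohydrate_zone(self):
        scheme = default_zones("fine")
        assert "956-1030" in scheme.labels  # band A
        assert "1030-1170" in scheme.labels  # band B
        assert scheme.zone_of(1072.0) == "1030-1170"

    def test_masks_partition_the_grid(self):
        scheme = default_zones("coarse")
        v = np.arange(650.0, 1801.0, 2.0)
        masks = scheme.masks(v)
        total = np.zeros(v.size, dtype=int)
        for m in masks:
            total += m.astype(int)
        assert np.all(total == 1)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            ZoneScheme(edges=(650.0, 600.0), labels=("bad",))
        with pytest.raises(ValueError):
            default_zones("medium")


class TestZoneFeatures:
    @pytest.fixture
    def fingerprint_set(self):
        grid = WavenumberGrid(np.arange(650.0, 1801.0, 2.0))
        rng = np.random.default_rng(0)
        return build_plain_set(rng.random((6, len(grid))), grid), grid

    def test_constant_spectrum_gives_constant_zone_means(self, fingerprint_set):
        data, grid = fingerprint_set
        data.intensities[0] = 0.7
        raw, _ = zone_features(data, default_zones("coarse"))
        np.testing.assert_allclose(raw[0], 0.7, atol=1e-12)

    def test_zone_indicator_spectrum_localizes(self, fingerprint_set):
        data, grid = fingerprint_set
        scheme = default_zones("coarse")
        masks = scheme.masks(grid.values)
        data.intensities[1] = 0.0
        data.intensities[1, masks[3]] = 2.0
        raw, _ = zone_features(data, scheme)
        assert raw[1, 3] == pytest.approx(2.0)
        others = [raw[1, j] for j in range(8) if j != 3]
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_normalization_maps_cohort_extremes_to_unit_interval(self, fingerprint_set):
        data, _ = fingerprint_set
        _, norm = zone_features(data, default_zones("coarse"))
        np.testing.assert_allclose(norm.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(norm.max(axis=0), 1.0, atol=1e-12)


class TestShapleyAxioms:
    def test_constant_model_gets_zero_attribution(self):
        rng = np.random.default_rng(1)
        attr = shapley_attribution(
            lambda rows: np.full(np.atleast_2d(rows).shape[0], 0.3),
            rng.random(6), rng.random((10, 6)),
        )
        np.testing.assert_allclose(attr.phi, 0.0, atol=1e-12)
        assert attr.baseline == pytest.approx(0.3)

    def test_linear_model_closed_form(self):
        # independent background: phi_i = w_i * (x_i - mean(background_i))
        rng = np.random.default_rng(2)
        w = rng.normal(size=8)
        x = rng.random(8)
        bg = rng.random((30, 8))
        attr = shapley_attribution(lambda rows: np.atleast_2d(rows) @ w, x, bg)
        np.testing.assert_allclose(attr.phi, w * (x - bg.mean(axis=0)), atol=1e-10)

    def test_local_accuracy_for_nonlinear_model(self):
        rng = np.random.default_rng(3)
        model = lambda rows: np.tanh(np.atleast_2d(rows).sum(axis=1)) ** 2
        x = rng.random(7)
        bg = rng.random((15, 7))
        attr = shapley_attribution(model, x, bg)
        assert attr.phi.sum() == pytest.approx(float(model(x[None])[0]) - attr.baseline,
                                               abs=1e-8)

    def test_dummy_zone_gets_zero(self):
        rng = np.random.default_rng(4)
        model = lambda rows: np.atleast_2d(rows)[:, 0] * 2.0  # ignores features 1..4
        attr = shapley_attribution(model, rng.random(5), rng.random((12, 5)))
        np.testing.assert_allclose(attr.phi[1:], 0.0, atol=1e-12)

    def test_symmetric_zones_get_equal_attribution(self):
        model = lambda rows: np.atleast_2d(rows)[:, 0] + np.atleast_2d(rows)[:, 1]
        x = np.array([0.8, 0.8, 0.1])
        bg = np.tile(np.array([0.2, 0.2, 0.5]), (5, 1))
        attr = shapley_attribution(model, x, bg)
        assert attr.phi[0] == pytest.approx(attr.phi[1], abs=1e-12)

    def test_sampled_mode_approximates_linear_closed_form(self):
        # 13 features forces the permutation-sampling path
        rng = np.random.default_rng(5)
        w = rng.normal(size=13)
        x = rng.random(13)
        bg = rng.random((10, 13))
        attr = shapley_attribution(
            lambda rows: np.atleast_2d(rows) @ w, x, bg, n_samples=400, seed=0
        )
        exact = w * (x - bg.mean(axis=0))
        assert attr.phi.sum() == pytest.approx(exact.sum(), abs=1e-8)
        np.testing.assert_allclose(attr.phi, exact, atol=0.15)


class TestGlobalSummary:
    def test_single_attribution_ranking(self):
        scheme = default_zones("coarse")
        from sialospec.zone_shap import ZoneAttribution

        phi = np.zeros(8)
        phi[2] = 0.5
        phi[5] = -0.2
        attr = ZoneAttribution("s", phi, np.zeros(8), 0.1)
        summary = summarize_global([attr], scheme)
        assert summary["ranking"][0] == scheme.labels[2]
        assert summary["ranking"][1] == scheme.labels[5]
        assert len(summary["points"]) == 8

    def test_all_zero_attributions_stable(self):
        scheme = default_zones("coarse")
        from sialospec.zone_shap import ZoneAttribution

        attrs = [ZoneAttribution("s", np.zeros(8), np.zeros(8), 0.0)]
        summary = summarize_global(attrs, scheme)
        assert set(summary["mean_abs_phi"].values()) == {0.0}

    def test_empty_attribution_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_global([], default_zones("coarse"))


class TestLocalizationOnSyntheticCohort:
    def test_injected_shift_zone_ranks_first(self):
        # disease effect only in 956-1210; the attribution must put that
        # zone at the top of the global ranking
        cfg = CohortConfig(
            n_control_donors=6, n_disease_donors=6, seed=77,
            disease_delta={(956.0, 1210.0): 0.04},
            ambiguity_fraction=0.0, baseline_scale=0.0, scatter_sd=0.0,
        )
        data, _ = generate_cohort(cfg)
        net_cfg = NetConfig(epochs=60, block_units=4, head_units=8, seed=1)
        net = train(build_net(net_cfg, len(data.grid)), data.intensities,
                    data.labels().astype(float), net_cfg)
        controls = data.subset_donors([d.donor_id for d in data.donors
                                       if d.label == "control"])
        disease_ids = [s for s, l in zip(data.spectrum_ids, data.labels()) if l == 1]
        subset = data.subset_spectra(disease_ids[:8])
        scheme = default_zones("coarse")
        attrs = attribute_set(net, subset, controls, scheme)
        summary = summarize_global(attrs, scheme)
        assert summary["ranking"][0] == "956-1210"
        # sign matches the injected positive shift
        idx = scheme.labels.index("956-1210")
        assert np.mean([a.phi[idx] for a in attrs]) > 0
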