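import numpy as np
import pytest

from genelang import (
    SyntheticConfig,
    euclidean_distances,
    generate_dataset,
    hamming_distances,
    mantel,
)
from genelang.distances import geographic_distances, haversine_km
from genelang.simulate import sample_coordinates, sample_frequencies, sample_traits


class TestCoordinates:
    def test_panel_counts_and_groups(self, small_config):
        panel = sample_coordinates(small_config, np.random.default_rng(0))
        assert panel.n == 12
        assert len(panel.group_ids("Indo-Iranian")) == 5
        assert len(panel.group_ids("European")) == 7

    def test_default_panel_mirrors_study_sizes(self):
        panel = sample_coordinates(SyntheticConfig(), np.random.default_rng(1))
        assert panel.n == 34
        assert len(panel.group_ids("Indo-Iranian")) == 11

    def test_points_inside_boxes(self):
        cfg = SyntheticConfig()
        for seed in range(50):
            panel = sample_coordinates(cfg, np.random.default_rng(seed))
            for group, box in (("Indo-Iranian", cfg.box_group1),
                               ("European", cfg.box_group2)):
                sub = panel.table.loc[panel.group_ids(group)]
                assert sub["latitude"].between(box[0], box[1]).all()
                assert sub["longitude"].between(box[2], box[3]).all()

    def test_deterministic_given_seed(self, small_config):
        p1 = sample_coordinates(small_config, np.random.default_rng(9))
        p2 = sample_coordinates(small_config, np.random.default_rng(9))
        assert p1.table.equals(p2.table)


class TestFrequencies:
    def test_rows_are_compositions(self, small_config):
        panel = sample_coordinates(small_config, np.random.default_rng(0))
        f = sample_frequencies(small_config, panel, "paternal",
                               np.random.default_rng(1))
        np.testing.assert_allclose(f.values.sum(axis=1), 1.0, atol=1e-12)
        assert (f.values >= 0).all()

    def test_infinite_lengthscale_makes_populations_identical(self):
        cfg = SyntheticConfig(lengthscale_km=1e9, freq_nugget=1e-6,
                              group_offset_paternal=0.0,
                              group_offset_maternal=0.0)
        dists = []
        for seed in range(30):
            panel = sample_coordinates(cfg, np.random.default_rng(seed))
            f = sample_frequencies(cfg, panel, "paternal",
                                   np.random.default_rng(1000 + seed))
            d = euclidean_distances(f)
            dists.append(d.condensed().mean())
        assert np.mean(dists) < 0.05

    def test_tiny_lengthscale_removes_geographic_signal(self):
        # nugget-dominated fields: Mantel r vs geography centred on zero
        cfg = SyntheticConfig(lengthscale_km=1e-6,
                              group_offset_paternal=0.0,
                              group_offset_maternal=0.0)
        rs = []
        for seed in range(100):
            panel = sample_coordinates(cfg, np.random.default_rng(seed))
            f = sample_frequencies(cfg, panel, "maternal",
                                   np.random.default_rng(5000 + seed))
            r = mantel(euclidean_distances(f),
                       geographic_distances(panel), n_perm=0).r
            rs.append(r)
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 0.01

    def test_deterministic_given_seed(self, small_config):
        panel = sample_coordinates(small_config, np.random.default_rng(0))
        f1 = sample_frequencies(small_config, panel, "paternal",
                                np.random.default_rng(3))
        f2 = sample_frequencies(small_config, panel, "paternal",
                                np.random.default_rng(3))
        np.testing.assert_array_equal(f1.values, f2.values)


class TestTraits:
    def _drivers(self, cfg, panel, rng):
        d_geo = haversine_km(panel.coordinates())
        d_pat = euclidean_distances(
            sample_frequencies(cfg, panel, "paternal", rng)).values
        d_mat = euclidean_distances(
            sample_frequencies(cfg, panel, "maternal", rng)).values
        return d_geo, d_pat, d_mat

    def test_all_weights_zero_warns_and_yields_exchangeable_traits(self):
        cfg = SyntheticConfig(w_geo_lexical=0, w_paternal_lexical=0,
                              w_maternal_lexical=0)
        panel = sample_coordinates(cfg, np.random.default_rng(0))
        drv = self._drivers(cfg, panel, np.random.default_rng(1))
        with pytest.warns(UserWarning, match="exchangeable"):
            t = sample_traits(cfg, panel, *drv, "lexical",
                              np.random.default_rng(2))
        assert t.values.shape == (34, 500)

    def test_hamming_increases_with_paternal_distance(self):
        # lexical system driven by the paternal distances only: binned
        # expected Hamming distance rises monotonically with the driver
        from scipy.stats import spearmanr

        cfg = SyntheticConfig(w_geo_lexical=0.0, w_paternal_lexical=1.0,
                              w_maternal_lexical=0.0, missing_rate_lexical=0.0)
        panel = sample_coordinates(cfg, np.random.default_rng(3))
        d_geo, d_pat, d_mat = self._drivers(cfg, panel, np.random.default_rng(4))
        t = sample_traits(cfg, panel, d_geo, d_pat, d_mat, "lexical",
                          np.random.default_rng(5))
        dh = hamming_distances(t).condensed()
        iu = np.triu_indices(panel.n, k=1)
        dp = d_pat[iu]
        bins = np.quantile(dp, np.linspace(0, 1, 11))
        idx = np.clip(np.digitize(dp, bins[1:-1]), 0, 9)
        means = [dh[idx == b].mean() for b in range(10)]
        rho, _ = spearmanr(range(10), means)
        assert rho > 0.9

    def test_missingness_rate_close_to_configured(self, small_config):
        cfg = SyntheticConfig(missing_rate_lexical=0.1)
        panel = sample_coordinates(cfg, np.random.default_rng(0))
        drv = self._drivers(cfg, panel, np.random.default_rng(1))
        t = sample_traits(cfg, panel, *drv, "lexical", np.random.default_rng(2))
        rate = t.mask.mean()
        assert abs(rate - 0.1) < 0.01

    def test_presence_frequency_matches_target(self):
        cfg = SyntheticConfig(missing_rate_lexical=0.0)
        panel = sample_coordinates(cfg, np.random.default_rng(0))
        drv = self._drivers(cfg, panel, np.random.default_rng(1))
        t = sample_traits(cfg, panel, *drv, "lexical", np.random.default_rng(2))
        assert t.values.mean() == pytest.approx(cfg.trait_presence_target,
                                                abs=0.03)


class TestGenerateDataset:
    def test_components_pass_loader_invariants(self, small_dataset, tmp_path):
        from genelang import io as glio

        paths = glio.write_dataset(small_dataset, tmp_path)
        glio.read_frequency_table(paths["freq_y"])
        glio.read_frequency_table(paths["freq_mt"])
        glio.read_trait_table(paths["lexicon"])
        glio.read_trait_table(paths["phonemes"])
        glio.read_population_panel(paths["panel"])

    def test_truth_holds_config_and_drivers(self, small_dataset):
        truth = small_dataset.truth
        assert truth["seed"] == 11
        assert truth["d_geo_km"].ids == small_dataset.panel.ids
        assert truth["config"]["n_lexical_traits"] == 80

    def test_deterministic_given_seed(self, small_config):
        d1 = generate_dataset(small_config, seed=21)
        d2 = generate_dataset(small_config, seed=21)
        np.testing.assert_array_equal(d1.freq_y.values, d2.freq_y.values)
        np.testing.assert_array_equal(d1.lexicon.values, d2.lexicon.values)
        np.testing.assert_array_equal(d1.lexicon.mask, d2.lexicon.mask)
        assert d1.panel.table.equals(d2.panel.table)

    def test_different_seeds_differ(self, small_config):
        d1 = generate_dataset(small_config, seed=1)
        d2 = generate_dataset(small_config, seed=2)
        assert not np.array_equal(d1.freq_y.values, d2.freq_y.values)
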