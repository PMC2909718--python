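import numpy as np
import pytest
from scipy import stats

import poolsim as ps


class TestBackground:
    def test_moments_at_scale(self, rng):
        cfg = ps.SimulationConfig()
        m = ps.draw_background(100, 1000, cfg, rng)
        assert m.shape == (100, 1000)
        n = m.size
        assert abs(m.mean() - 8.0) < 3 * 0.2 / np.sqrt(n)
        assert abs(m.std(ddof=1) - 0.2) < 3 * 0.2 / np.sqrt(2 * n)

    def test_degenerate_variance_limit(self, rng):
        cfg = ps.SimulationConfig(bio_sd=1e-12)
        m = ps.draw_background(5, 4, cfg, rng)
        assert np.allclose(m, 8.0, atol=1e-9)

    @pytest.mark.parametrize("shape", [(0, 3), (3, 0), (-1, 2)])
    def test_bad_dimensions(self, rng, shape):
        with pytest.raises(ValueError):
            ps.draw_background(*shape, ps.SimulationConfig(), rng)


class TestDEBlock:
    def test_deltas_within_interval(self, rng):
        cfg = ps.SimulationConfig()
        _, deltas = ps.simulate_de_block(cfg, rng)
        assert deltas.shape == (10,)
        assert np.all((deltas >= 0.1) & (deltas <= 0.5))

    def test_class_difference_converges_to_delta(self, rng):
        n = 10_000
        cfg = ps.SimulationConfig(n_per_class=n, n_features=10)
        block, deltas = ps.simulate_de_block(cfg, rng)
        diff = block[n:].mean(axis=0) - block[:n].mean(axis=0)
        tol = 3 * cfg.bio_sd * np.sqrt(2 / n)
        assert np.all(np.abs(diff - deltas) < tol)

    def test_null_effect_indistinguishable(self, rng):
        cfg = ps.SimulationConfig(de_delta_interval=(0.0, 0.0))
        block, deltas = ps.simulate_de_block(cfg, rng)
        assert np.all(deltas == 0)
        res = stats.ttest_ind(block[:30], block[30:], axis=0)
        # no column should be extreme at Bonferroni level
        assert res.pvalue.min() > 0.005 / 10


class TestPatternBlock:
    def test_linear_identities_exact(self, rng):
        cfg = ps.SimulationConfig(scenario="linear_only")
        block, pairing = ps.simulate_pattern_block(cfg, rng)
        n = cfg.n_per_class
        for g1, g2 in pairing:
            np.testing.assert_array_equal(block[:n, g2], 2 * block[:n, g1])
            np.testing.assert_allclose(
                block[n:, g2] - 2 * block[n:, g1], cfg.pattern_offset, rtol=0, atol=1e-12
            )

    def test_second_gene_class_difference(self, rng):
        # construction implies E[g2 | B] - E[g2 | A] = delta = 0.4
        cfg = ps.SimulationConfig(
            scenario="linear_only", n_per_class=2000, n_patterns=20, n_features=40
        )
        block, pairing = ps.simulate_pattern_block(cfg, rng)
        n = cfg.n_per_class
        g2_cols = [g2 for _, g2 in pairing]
        diffs = block[n:, g2_cols].mean(axis=0) - block[:n, g2_cols].mean(axis=0)
        se = 2 * cfg.bio_sd * np.sqrt(2 / n)
        assert abs(diffs.mean() - 0.4) < 3 * se / np.sqrt(len(g2_cols))


class TestNoise:
    def test_zero_noise_is_identity(self, rng):
        x = rng.normal(size=(5, 7))
        y = ps.add_technical_noise(x, 0.0, rng)
        np.testing.assert_array_equal(x, y)
        assert y is not x

    @pytest.mark.parametrize("sd,var", [(0.2, 0.04), (0.4, 0.16)])
    def test_noise_variance_levels(self, rng, sd, var):
        x = np.zeros((100, 1000))
        eps = ps.add_technical_noise(x, sd, rng) - x
        assert np.isclose(eps.var(ddof=1), var, rtol=0.02)

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.add_technical_noise(np.zeros((2, 2)), -0.1, rng)

    def test_pattern_pair_noise_variance(self, rng):
        # Y_g2 - 2 Y_g1 = delta*1_B + (eps_g2 - 2 eps_g1), variance 5 sigma_eps^2
        cfg = ps.SimulationConfig(
            scenario="linear_only", n_per_class=2000, n_patterns=20, n_features=40
        )
        ds = ps.sample_dataset(cfg, ps.draw_scenario_params(cfg, rng), rng)
        g1 = ds.truth.index[ds.truth["role"] == "pattern_g1"].to_numpy()
        g2 = ds.truth.index[ds.truth["role"] == "pattern_g2"].to_numpy()
        resid = ds.Y[:, g2] - 2 * ds.Y[:, g1]
        v = resid[: cfg.n_per_class].var(ddof=1)
        assert np.isclose(v, 5 * cfg.noise_sd**2, rtol=0.05)


class TestAssemble:
    @pytest.mark.parametrize(
        "scenario,counts",
        [
            ("de_only", {"de": 10, "background": 990}),
            ("linear_only", {"pattern_g1": 10, "pattern_g2": 10, "background": 980}),
            (
                "combined",
                {"de": 10, "pattern_g1": 10, "pattern_g2": 10, "background": 970},
            ),
        ],
    )
    def test_role_counts(self, scenario, counts):
        ds = ps.assemble_dataset(ps.SimulationConfig(scenario=scenario, seed=1))
        assert ds.Y.shape == (60, 1000)
        assert ds.X.shape == ds.Y.shape
        assert ds.truth["role"].value_counts().to_dict() == counts
        assert (ds.labels == "A").sum() == 30 and (ds.labels == "B").sum() == 30

    def test_determinism_bit_identical(self):
        cfg = ps.SimulationConfig(scenario="combined", seed=77)
        d1, d2 = ps.assemble_dataset(cfg), ps.assemble_dataset(cfg)
        np.testing.assert_array_equal(d1.X, d2.X)
        np.testing.assert_array_equal(d1.Y, d2.Y)

    def test_shuffled_columns_keep_truth_aligned(self):
        cfg = ps.SimulationConfig(scenario="combined", seed=3, shuffle_columns=True)
        ds = ps.assemble_dataset(cfg)
        n = cfg.n_per_class
        truth = ds.truth
        for k in range(cfg.n_patterns):
            g1 = truth.index[(truth["role"] == "pattern_g1") & (truth["pattern"] == k)][0]
            g2 = truth.index[(truth["role"] == "pattern_g2") & (truth["pattern"] == k)][0]
            np.testing.assert_allclose(ds.X[:n, g2], 2 * ds.X[:n, g1], atol=1e-12)

    def test_background_columns_carry_no_class_signal(self, rng):
        # t-test p-values on background columns should be ~ U(0, 1)
        cfg = ps.SimulationConfig(n_features=1100, scenario="de_only", seed=5)
        ds = ps.assemble_dataset(cfg)
        bg = ds.truth.index[ds.truth["role"] == "background"].to_numpy()
        res = stats.ttest_ind(ds.Y[:30][:, bg], ds.Y[30:][:, bg], axis=0)
        ks = stats.kstest(res.pvalue, "uniform")
        assert len(bg) >= 1000
        assert ks.pvalue > 0.01


class TestIO:
    def test_tsv_round_trip_lossless(self, tmp_path, small_cfg):
        ds = ps.assemble_dataset(small_cfg.with_(seed=9, scenario="combined"))
        ps.write_dataset(ds, tmp_path)
        back = ps.read_dataset(tmp_path)
        np.testing.assert_allclose(back.X, ds.X, rtol=1e-14, atol=1e-14)
        np.testing.assert_allclose(back.Y, ds.Y, rtol=1e-14, atol=1e-14)
        np.testing.assert_array_equal(back.labels, ds.labels)
        assert list(back.truth["role"]) == list(ds.truth["role"])
        np.testing.assert_allclose(
            back.truth["delta"].to_numpy(), ds.truth["delta"].to_numpy(),
            rtol=1e-14, equal_nan=True,
        )
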