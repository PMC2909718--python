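import itertools

import numpy as np
import pandas as pd
import pytest

import poolsim as ps


def tiny_run_cfg(tmp_dir=None, **kwargs):
    sim = ps.SimulationConfig(n_per_class=10, n_features=60, n_de_genes=10)
    defaults = dict(
        simulation=sim,
        scenarios=("de_only",),
        noise_sds=(0.2,),
        pool_sizes=(1, 2, 5),
        methods=("svml", "ttest_lda"),
        n_reps=3,
        base_seed=123,
        n_boot=100,
        out_dir=str(tmp_dir) if tmp_dir else None,
    )
    defaults.update(kwargs)
    return ps.RunConfig(**defaults)


class TestPredictionError:
    def test_arithmetic(self):
        a = np.repeat(["A", "B"], 30)
        assert ps.prediction_error(a, a) == 0.0
        assert ps.prediction_error(a, np.where(a == "A", "B", "A")) == 1.0
        b = a.copy()
        b[:3] = "B"
        assert ps.prediction_error(b, a) == pytest.approx(0.05)  # 3 of 60

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            ps.prediction_error(["A"], ["A", "B"])
        with pytest.raises(ValueError):
            ps.prediction_error([], [])


class TestBootstrapCI:
    def test_degenerate_all_equal(self, rng):
        lo, hi = ps.bootstrap_ci(np.full(20, 0.3), rng=rng)
        assert lo == hi == pytest.approx(0.3)

    def test_contains_sample_mean(self, rng):
        e = rng.uniform(0, 1, size=50)
        lo, hi = ps.bootstrap_ci(e, rng=rng)
        assert lo <= e.mean() <= hi

    def test_matches_normal_theory_width(self, rng):
        e = rng.normal(0.2, 0.01, size=500)
        lo, hi = ps.bootstrap_ci(e, level=0.95, n_boot=2000, rng=rng)
        expected = 2 * 1.96 * e.std(ddof=1) / np.sqrt(len(e))
        assert abs((hi - lo) - expected) / expected < 0.15

    def test_width_shrinks_with_sqrt_n(self, rng):
        e = rng.normal(0.3, 0.05, size=800)
        w1 = np.diff(ps.bootstrap_ci(e[:200], n_boot=2000, rng=rng))[0]
        w2 = np.diff(ps.bootstrap_ci(e, n_boot=2000, rng=rng))[0]
        assert 0.35 < w2 / w1 < 0.65  # ~ 1/2 for 4x the repetitions

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.bootstrap_ci([], rng=rng)


class TestSingleRepetition:
    def test_deterministic_under_seed(self):
        cfg = ps.SimulationConfig(n_per_class=10, n_features=60)
        r1 = ps.run_single_repetition(cfg, 2, "ttest_lda", 99)
        r2 = ps.run_single_repetition(cfg, 2, "ttest_lda", 99)
        assert r1 == r2

    def test_error_granularity(self):
        cfg = ps.SimulationConfig(n_per_class=10, n_features=60)
        rec = ps.run_single_repetition(cfg, 1, "svml", 5)
        assert rec["n_test"] == 20
        assert (rec["error"] * 20) == pytest.approx(round(rec["error"] * 20))

    @pytest.mark.parametrize("method", ps.METHODS)
    def test_huge_effect_perfectly_classified(self, method):
        cfg = ps.SimulationConfig(
            n_per_class=10, n_features=40, noise_sd=0.0,
            de_delta_interval=(5.0, 5.0),
        )
        clf_cfg = ps.ClassifierConfig(n_trees=50)
        rec = ps.run_single_repetition(cfg, 2, method, 7, clf_cfg)
        assert rec["error"] == 0.0


class TestRunExperiment:
    def test_record_and_summary_shapes(self, tmp_path):
        res = ps.run_experiment(tiny_run_cfg())
        assert len(res.records) == 3 * 2 * 3  # reps x methods x pool sizes
        assert set(res.records["m_p"]) == {1, 2, 5}
        # four summaries per method when four pool sizes are run
        assert len(res.summary) == 2 * 3
        for (m, mp), grp in res.records.groupby(["method", "m_p"]):
            row = res.summary[(res.summary["method"] == m) & (res.summary["m_p"] == mp)]
            assert row["mean_error"].iloc[0] == pytest.approx(grp["error"].mean())
            assert row["ci_lower"].iloc[0] <= row["mean_error"].iloc[0]
            assert row["mean_error"].iloc[0] <= row["ci_upper"].iloc[0]

    def test_full_reproducibility(self):
        r1 = ps.run_experiment(tiny_run_cfg())
        r2 = ps.run_experiment(tiny_run_cfg())
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_resume_skips_complete_cells(self, tmp_path):
        cfg = tiny_run_cfg(tmp_dir=tmp_path)
        r1 = ps.run_experiment(cfg)
        (tmp_path / "records.csv").touch()  # would be re-read, not recomputed
        r2 = ps.run_experiment(cfg)
        pd.testing.assert_frame_equal(
            r1.records.reset_index(drop=True),
            r2.records.reset_index(drop=True),
            check_dtype=False,
        )

    def test_errors_bounded(self):
        res = ps.run_experiment(tiny_run_cfg())
        assert res.records["error"].between(0, 1).all()


class TestSummarize:
    def _synthetic_records(self):
        rows = []
        for scen, noise, method, m_p, rep in itertools.product(
            ps.SCENARIOS, (0.2, 0.4), ps.METHODS, (1, 2, 3, 5), range(2)
        ):
            rows.append({
                "scenario": scen, "noise_sd": noise, "method": method,
                "m_p": m_p, "rep": rep, "n_test": 60, "tuning": "{}",
                "error": 0.1 * m_p + 0.01 * rep,
            })
        return pd.DataFrame(rows)

    def test_full_grid_has_120_rows(self):
        summary = ps.summarize(self._synthetic_records(), n_boot=50)
        assert len(summary) == 3 * 2 * 5 * 4
        assert summary["mean_error"].between(0, 1).all()

    def test_degradation_ratio_column(self):
        summary = ps.summarize(self._synthetic_records(), n_boot=50)
        # errors scale linearly with m_p here, so the m5/m1 ratio is 5x
        np.testing.assert_allclose(
            summary["ratio_mp5_vs_mp1"], 0.505 / 0.105, rtol=1e-12
        )

    def test_deterministic_ordering(self):
        summary = ps.summarize(self._synthetic_records(), n_boot=50)
        assert list(summary["scenario"].unique()) == list(ps.SCENARIOS)
        first_block = summary.iloc[:4]
        assert list(first_block["m_p"]) == [1, 2, 3, 5]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.summarize(pd.DataFrame())


class TestPlot:
    def test_bar_chart_renders(self):
        import matplotlib
        matplotlib.use("Agg")
        res = ps.run_experiment(tiny_run_cfg())
        ax = ps.plot_summary(res.summary, "de_only", 0.2)
        assert len(ax.patches) == 2 * 3  # methods x pool sizes bars
        with pytest.raises(ValueError):
            ps.plot_summary(res.summary, "combined", 0.2)
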