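import numpy as np
import pytest

from healthdea.dea import (
    DEAConfig, TwoStageNetworkDEA, ccr_efficiency, decompose_stages,
    relational_overall, run_dea_year,
)
from healthdea.panel import PanelError, positivize_indicators
from healthdea.synthetic import SyntheticDEAConfig, generate_dea_panel

from oracles import ccr_ratio_oracle, relational_ratio_oracle


class TestCCR:
    def test_single_dimension_reduces_to_ratio_to_best(self):
        X = np.array([[1.0], [1.0]])
        Y = np.array([[4.0], [1.0]])
        assert ccr_efficiency(X, Y, 0)[0] == pytest.approx(1.0, abs=1e-9)
        assert ccr_efficiency(X, Y, 1)[0] == pytest.approx(0.25, abs=1e-9)

    def test_dominant_unit_is_frontier(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 2, (5, 2))
        Y = rng.uniform(1, 2, (5, 2))
        X[0] = X.min(axis=0) * 0.9   # best in every input
        Y[0] = Y.max(axis=0) * 1.1   # best in every output
        assert ccr_efficiency(X, Y, 0)[0] == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_ratio_form_grid_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0.5, 3, (4, 2))
        Y = rng.uniform(0.5, 3, (4, 1))
        lp = np.array([ccr_efficiency(X, Y, k)[0] for k in range(4)])
        oracle = ccr_ratio_oracle(X, Y, g=1001)
        assert np.abs(lp - oracle).max() < 1e-3

    def test_multipliers_respect_epsilon_bound(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.5, 3, (4, 2))
        Y = rng.uniform(0.5, 3, (4, 2))
        cfg = DEAConfig(epsilon=1e-6)
        _, v, u, _ = ccr_efficiency(X, Y, 0, cfg)
        assert np.all(v >= 1e-6 / X.max(axis=0) - 1e-12)
        assert np.all(u >= 1e-6 / Y.max(axis=0) - 1e-12)


class TestRelational:
    def test_chain_example(self, chain_instance):
        X, Z, Y = chain_instance
        scores = [relational_overall(X, Z, Y, k)[0] for k in range(3)]
        assert scores == pytest.approx([1.0, 0.25, 0.25], abs=1e-9)

    def test_relational_bounded_by_independent(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.5, 3, (6, 1))
        Z = rng.uniform(0.5, 3, (6, 2))
        Y = rng.uniform(0.5, 3, (6, 2))
        for k in range(6):
            rel = relational_overall(X, Z, Y, k)[0]
            ind = ccr_efficiency(X, Y, k)[0]
            assert rel <= ind + 1e-9

    def test_agrees_with_multistart_nonlinear_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0.5, 3, (6, 1))
        Z = rng.uniform(0.5, 3, (6, 2))
        Y = rng.uniform(0.5, 3, (6, 2))
        for k in (0, 3):
            lp = relational_overall(X, Z, Y, k)[0]
            oracle = relational_ratio_oracle(X, Z, Y, k, n_starts=60, seed=k)
            assert lp == pytest.approx(oracle, abs=1e-4)


class TestDecomposition:
    def test_chain_stage_split(self, chain_instance):
        X, Z, Y = chain_instance
        e = relational_overall(X, Z, Y, 1)[0]
        e1, e2, _ = decompose_stages(X, Z, Y, 1, e)
        assert (e1, e2) == pytest.approx((0.5, 0.5), abs=1e-9)

    def test_efficient_unit_has_efficient_stages(self, chain_instance):
        X, Z, Y = chain_instance
        e = relational_overall(X, Z, Y, 0)[0]
        e1, e2, _ = decompose_stages(X, Z, Y, 0, e)
        assert e1 == pytest.approx(1.0, abs=1e-8)
        assert e2 == pytest.approx(1.0, abs=1e-8)

    def test_product_identity_both_priorities(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0.5, 3, (5, 1))
        Z = rng.uniform(0.5, 3, (5, 2))
        Y = rng.uniform(0.5, 3, (5, 2))
        for k in range(5):
            e = relational_overall(X, Z, Y, k)[0]
            for prio in ("stage1_first", "stage2_first"):
                e1, e2, _ = decompose_stages(X, Z, Y, k, e, priority=prio)
                assert abs(e - e1 * e2) <= 1e-6
                assert 0 < e1 <= 1 + 1e-9
                assert 0 < e2 <= 1 + 1e-9


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(21)
    return (rng.uniform(0.5, 3, (6, 1)), rng.uniform(0.5, 3, (6, 3)),
            rng.uniform(0.5, 3, (6, 2)))


class TestInvariances:
    def test_units_invariance_per_column(self, instance):
        X, Z, Y = instance
        base = TwoStageNetworkDEA().fit(X, Z, Y)
        for mat, col, factor in [("Z", 1, 1000.0), ("Y", 0, 0.001),
                                 ("X", 0, 37.0)]:
            Xs, Zs, Ys = X.copy(), Z.copy(), Y.copy()
            {"X": Xs, "Z": Zs, "Y": Ys}[mat][:, col] *= factor
            scaled = TwoStageNetworkDEA().fit(Xs, Zs, Ys)
            assert np.abs(scaled.overall_ - base.overall_).max() <= 1e-8
            assert np.abs(scaled.stage1_ - base.stage1_).max() <= 1e-8

    def test_dominance_monotonicity(self, instance):
        X, Z, Y = instance
        before = relational_overall(X, Z, Y, 2)[0]
        Y2 = Y.copy()
        Y2[2] *= 1.3   # strictly more final output, all else equal
        after = relational_overall(X, Z, Y2, 2)[0]
        assert after >= before - 1e-9

    def test_frontier_nonempty_each_stage(self, instance):
        model = TwoStageNetworkDEA().fit(*instance)
        assert model.stage1_.max() >= 1 - 1e-6
        assert model.stage2_alt_.max() >= 1 - 1e-6


class TestRunYear:
    def test_identical_units_all_efficient(self):
        panel, _ = generate_dea_panel(
            SyntheticDEAConfig(n_units=4, n_years=1, n_frontier=4, seed=2))
        scores = run_dea_year(positivize_indicators(panel), 2009)
        for col in ("overall", "stage1", "stage2"):
            assert np.allclose(scores[col], 1.0, atol=1e-7)

    def test_doubled_input_halves_stage1(self):
        panel, truth = generate_dea_panel(
            SyntheticDEAConfig(n_units=6, n_years=1, n_frontier=3, seed=8))
        pos = positivize_indicators(panel)
        # clone a frontier unit with doubled expenditure
        front = truth[truth["frontier"]].iloc[0]["unit"]
        clone = pos[pos["unit"] == front].copy()
        clone["unit"] = "clone"
        clone["I1"] *= 2.0
        import pandas as pd
        pos2 = pd.concat([pos, clone], ignore_index=True)
        pos2.attrs["positivized"] = True
        scores = run_dea_year(pos2, 2009).set_index("unit")
        assert scores.loc["clone", "stage1"] == pytest.approx(
            scores.loc[front, "stage1"] / 2.0, abs=1e-7)

    def test_recovers_generator_stage1_truth(self):
        panel, truth = generate_dea_panel(
            SyntheticDEAConfig(n_units=10, n_years=2, seed=7))
        scores = run_dea_year(positivize_indicators(panel), 2010)
        merged = scores.merge(truth, on=["unit", "year"])
        rmse = np.sqrt(np.mean((merged["stage1"] - merged["stage1_true"]) ** 2))
        assert rmse < 0.01

    def test_unpositivized_panel_rejected(self):
        panel, _ = generate_dea_panel(
            SyntheticDEAConfig(n_units=4, n_years=1, seed=2))
        with pytest.raises(PanelError, match="positivized"):
            run_dea_year(panel, 2009)
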