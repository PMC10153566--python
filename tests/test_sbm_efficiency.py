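import numpy as np
import pytest

from healthdea import (
    RTS,
    GeneratorConfig,
    combined_score,
    generate_panel,
    projection_report,
    sbm_score,
    score_matrix,
    super_sbm_score,
)
from healthdea.panel_io import CrossSection, PanelDataset, PanelSchema

from conftest import random_section, sbm_grid_oracle


def section(X, Y):
    X, Y = np.atleast_2d(np.asarray(X, float)), np.atleast_2d(np.asarray(Y, float))
    return CrossSection(period=0, dmus=tuple(f"d{i}" for i in range(len(X))), X=X, Y=Y)


class TestSBMToys:
    def test_dominated_dmu_score_and_slacks(self, toy_section):
        r = sbm_score(1, toy_section, RTS.VRS)
        assert r.rho == pytest.approx(0.5, abs=1e-8)
        assert r.input_slacks[0] == pytest.approx(2.0, abs=1e-7)
        assert r.output_slacks[0] == pytest.approx(0.0, abs=1e-7)
        assert r.lambdas[0] == pytest.approx(1.0, abs=1e-7)

    def test_undominated_dmu_scores_one(self, toy_section):
        r = sbm_score(0, toy_section, RTS.VRS)
        assert r.rho == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(r.input_slacks, 0, atol=1e-7)
        assert np.allclose(r.output_slacks, 0, atol=1e-7)

    def test_duplicate_of_frontier_dmu_scores_one(self):
        sec = section([[2.0], [2.0], [4.0]], [[2.0], [2.0], [2.0]])
        assert sbm_score(1, sec, RTS.VRS).rho == pytest.approx(1.0, abs=1e-8)

    def test_feasibility_identities_at_optimum(self):
        rng = np.random.default_rng(3)
        sec = random_section(rng, n=5, m=2, s=2)
        for k in range(5):
            r = sbm_score(k, sec, RTS.VRS)
            np.testing.assert_allclose(
                sec.X.T @ r.lambdas + r.input_slacks, sec.X[k], atol=1e-7
            )
            np.testing.assert_allclose(
                sec.Y.T @ r.lambdas - r.output_slacks, sec.Y[k], atol=1e-7
            )


class TestSuperSBMToys:
    def test_frontier_dmu_super_score(self, toy_section):
        r = super_sbm_score(0, toy_section, RTS.VRS)
        assert r.delta == pytest.approx(2.0, abs=1e-8)
        assert r.projection_inputs[0] == pytest.approx(4.0, abs=1e-6)
        assert r.projection_outputs[0] == pytest.approx(2.0, abs=1e-6)

    def test_twin_dmus_score_exactly_one(self):
        sec = section([[2.0], [2.0]], [[2.0], [2.0]])
        for k in (0, 1):
            assert super_sbm_score(k, sec, RTS.VRS).delta == pytest.approx(1.0, abs=1e-8)

    def test_unique_max_output_dmu_remains_scorable(self):
        # the others' convex hull cannot reach its output, but the projection
        # point may lower its own output, so the program stays feasible with
        # delta >= 1 (the non-oriented super score has no VRS feasibility gap)
        sec = section([[1.0], [1.0]], [[10.0], [1.0]])
        r = super_sbm_score(0, sec, RTS.VRS)
        assert r.status == "optimal" and r.delta >= 1.0 - 1e-6
        assert r.projection_outputs[0] <= 10.0 + 1e-7

    def test_delta_bounds_and_projections(self):
        rng = np.random.default_rng(5)
        sec = random_section(rng, n=6, m=2, s=2)
        for k in range(6):
            base = sbm_score(k, sec, RTS.VRS)
            if not base.efficient:
                continue
            r = super_sbm_score(k, sec, RTS.VRS)
            assert r.status == "optimal"
            assert r.delta >= 1.0 - 1e-6
            assert np.all(r.projection_inputs >= sec.X[k] - 1e-6)
            assert np.all(r.projection_outputs <= sec.Y[k] + 1e-6)
            assert np.all(r.projection_outputs > 0)


class TestCombinedScore:
    def test_routing(self, toy_section):
        assert combined_score(1, toy_section, RTS.VRS) == (pytest.approx(0.5), "sbm")
        val, flag = combined_score(0, toy_section, RTS.VRS)
        assert flag == "super" and val == pytest.approx(2.0)


class TestProperties:
    def test_rho_one_iff_zero_slacks(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            sec = random_section(rng, n=5, m=2, s=2)
            for k in range(5):
                r = sbm_score(k, sec, RTS.VRS)
                zero_slack = np.all(r.input_slacks <= 1e-6) and np.all(r.output_slacks <= 1e-6)
                assert (r.rho >= 1 - 1e-6) == zero_slack
                assert 0 < r.rho <= 1 + 1e-9

    def test_unit_invariance_of_rho_and_delta(self):
        rng = np.random.default_rng(23)
        sec = random_section(rng, n=5, m=2, s=2)
        sx, sy = np.array([50.0, 0.02]), np.array([3.0, 400.0])
        scaled = CrossSection(0, sec.dmus, sec.X * sx, sec.Y * sy)
        for k in range(5):
            r0, r1 = sbm_score(k, sec, RTS.VRS), sbm_score(k, scaled, RTS.VRS)
            assert r1.rho == pytest.approx(r0.rho, abs=1e-7)
            if r0.efficient:
                d0 = super_sbm_score(k, sec, RTS.VRS).delta
                d1 = super_sbm_score(k, scaled, RTS.VRS).delta
                assert d1 == pytest.approx(d0, abs=1e-7)

    def test_more_input_never_raises_rho(self):
        rng = np.random.default_rng(29)
        sec = random_section(rng, n=6, m=2, s=1)
        rhos = [sbm_score(k, sec, RTS.VRS) for k in range(6)]
        k = int(np.argmin([r.rho for r in rhos]))  # a clearly dominated DMU
        for bump in (1.1, 1.5, 3.0):
            X = sec.X.copy()
            X[k, 0] *= bump
            worse = sbm_score(k, CrossSection(0, sec.dmus, X, sec.Y), RTS.VRS)
            assert worse.rho <= rhos[k].rho + 1e-7

    def test_super_delta_grows_as_frontier_dmu_leaves_hull(self, toy_section):
        base = super_sbm_score(0, toy_section, RTS.VRS).delta
        X = toy_section.X.copy()
        X[0, 0] *= 0.5  # frontier DMU uses even less input
        further = super_sbm_score(0, CrossSection(0, toy_section.dmus, X, toy_section.Y), RTS.VRS)
        assert further.delta >= base - 1e-7

    @pytest.mark.parametrize("seed", range(8))
    def test_lp_matches_simplex_grid_oracle(self, seed):
        """Spot check of the LP against the brute-force simplex-grid oracle."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(2, 4))
        m = int(rng.integers(1, 3))
        s = int(rng.integers(1, 3))
        sec = random_section(rng, n=n, m=m, s=s)
        k = int(rng.integers(0, n))
        lp = sbm_score(k, sec, RTS.VRS).rho
        oracle = sbm_grid_oracle(k, sec)
        assert lp == pytest.approx(oracle, abs=2e-3)


class TestScoreMatrix:
    def test_identical_dmus_all_score_one(self):
        sch = PanelSchema(("x",), ("y",))
        n, T = 4, 3
        X = np.full((n, T, 1), 2.0)
        Y = np.full((n, T, 1), 3.0)
        panel = PanelDataset(tuple(f"d{i}" for i in range(n)), (0, 1, 2), X, Y,
                             np.zeros((n, T, 0)), sch)
        mat = score_matrix(panel, RTS.VRS)
        np.testing.assert_allclose(mat.scores, 1.0, atol=1e-7)
        np.testing.assert_allclose(mat.dmu_means, 1.0, atol=1e-7)
        np.testing.assert_allclose(mat.period_means, 1.0, atol=1e-7)
        assert mat.grand_mean == pytest.approx(1.0, abs=1e-7)

    def test_generated_frontier_members_score_at_least_one(self, small_panel):
        panel, truth = small_panel
        mat = score_matrix(panel, RTS.VRS)
        assert np.nanmin(mat.scores[truth.frontier]) >= 1 - 1e-6

    def test_means_are_arithmetic_over_cells(self, small_panel):
        panel, _ = small_panel
        mat = score_matrix(panel, RTS.VRS)
        np.testing.assert_allclose(mat.dmu_means, mat.scores.mean(axis=1))
        assert mat.grand_mean == pytest.approx(mat.scores.mean())
        frame = mat.to_frame(decimals=3)
        assert frame.loc["Mean", "Mean"] == pytest.approx(round(mat.grand_mean, 3))


@pytest.fixture(scope="module")
def toy_panel():
    sch = PanelSchema(("staff",), ("visits",))
    X = np.array([[[2.0]], [[4.0]]])
    Y = np.array([[[2.0]], [[2.0]]])
    return PanelDataset(("A", "B"), (2018,), X, Y, np.zeros((2, 1, 0)), sch)


class TestProjectionReport:

    def test_efficient_dmu_excluded(self, toy_panel):
        report = projection_report(toy_panel, 2018, RTS.VRS)
        assert "A" not in report.table.index

    def test_dominated_dmu_amounts_and_percentages(self, toy_panel):
        tab = projection_report(toy_panel, 2018, RTS.VRS).rounded()
        row = tab.loc["B"]
        assert row["staff_redundancy"] == pytest.approx(2.0, abs=1e-6)
        assert row["staff_pct"] == 50.00
        assert row["visits_shortage"] == pytest.approx(0.0, abs=1e-6)
        assert row["visits_pct"] == 0.00

    def test_percentage_bounds(self, small_panel):
        panel, _ = small_panel
        report = projection_report(panel, panel.periods[-1], RTS.VRS)
        for name in panel.schema.input_names:
            pct = report.table[f"{name}_pct"]
            assert ((pct >= 0) & (pct < 100)).all()
        # zero slack => zero percentage
        for name in (*panel.schema.input_names, *panel.schema.output_names):
            amt_col = [c for c in report.table.columns if c.startswith(name) and not c.endswith("_pct")][0]
            zero = report.table[amt_col] <= 1e-9
            assert (report.table.loc[zero, f"{name}_pct"] <= 1e-9).all()
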