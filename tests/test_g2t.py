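"""Allometric genome-to-T model: fit, error curve, assignment, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsidarch.g2t import (
    ELONGATED,
    CapsidRecord,
    GenomeToTModel,
    GenomeToTResults,
    compare_alternative_models,
    fit_error_decay,
    fit_g2t,
    mre_curve,
    theoretical_exponent,
)
from capsidarch.lattice import enumerate_architectures
from capsidarch.simulate import simulate_g2t_records


def make_fit(a: float, b: float) -> GenomeToTResults:
    return GenomeToTResults(
        model=None, a=a, ln_b=float(np.log(b)), r2=1.0, n=0,
        residuals_ln=np.array([]),
    )


class TestFit:
    def test_table_fixture_exponent_and_r2(self, g2t_fit):
        assert g2t_fit.n == 37
        assert g2t_fit.a == pytest.approx(0.71, abs=0.03)
        assert g2t_fit.r2 == pytest.approx(0.98, abs=0.01)

    def test_noiseless_power_law_recovered_exactly(self):
        recs = [
            CapsidRecord(f"p{i}", t_value=2.0 * g ** (2 / 3), genome_kbp=g)
            for i, g in enumerate([10.0, 30.0, 90.0, 270.0])
        ]
        fit = fit_g2t(recs)
        assert fit.a == pytest.approx(2 / 3, abs=1e-12)
        assert fit.b == pytest.approx(2.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_simulated_records_recover_exponent(self):
        # average recovered exponent over replicates stays near the truth
        fits = [
            fit_g2t(simulate_g2t_records(200, a_true=0.67, noise_sd=0.1, seed=s)).a
            for s in range(30)
        ]
        assert np.mean(fits) == pytest.approx(0.67, abs=0.01)
        assert all(abs(a - 0.67) < 0.03 for a in fits)

    def test_fit_is_deterministic(self, highres_records):
        f1, f2 = fit_g2t(highres_records), fit_g2t(highres_records)
        assert f1.a == f2.a and f1.ln_b == f2.ln_b and f1.r2 == f2.r2

    def test_rejects_too_few_or_nonpositive(self):
        with pytest.raises(ValueError):
            GenomeToTModel([7, 7], [40, 41])
        with pytest.raises(ValueError):
            GenomeToTModel([7, -1, 9], [40, 41, 42])

    def test_from_dataframe_matches_records(self, highres_records, g2t_fit):
        from capsidarch.g2t import records_to_frame

        fit = GenomeToTModel.from_dataframe(records_to_frame(highres_records)).fit()
        assert fit.a == g2t_fit.a


class TestAlternativeModels:
    def test_power_wins_on_fixture(self, highres_records):
        table = compare_alternative_models(highres_records)
        power_r2 = table.loc[table["model"] == "power", "r2"].item()
        assert power_r2 >= table["r2"].max() - 1e-12
        assert table.loc[table["model"] == "power", "best"].item()

    def test_exact_power_law(self):
        recs = [
            CapsidRecord(f"p{i}", 0.5 * g**0.7, g)
            for i, g in enumerate(np.geomspace(15, 500, 20))
        ]
        table = compare_alternative_models(recs).set_index("model")
        assert table.loc["power", "r2"] == pytest.approx(1.0, abs=1e-10)
        assert table.loc["logarithmic", "r2"] < 1.0 - 1e-6

    def test_exact_quadratic_data(self):
        recs = [
            CapsidRecord(f"p{i}", 2.0 + 0.001 * g**2, g)
            for i, g in enumerate(np.linspace(20, 400, 20))
        ]
        table = compare_alternative_models(recs).set_index("model")
        assert table.loc["quadratic", "r2"] >= table["r2"].max() - 1e-12

    def test_singular_design_raises(self):
        recs = [CapsidRecord(f"p{i}", 7.0, 40.0) for i in range(5)]
        with pytest.raises(ValueError, match="singular"):
            compare_alternative_models(recs)


class TestPredict:
    @pytest.mark.parametrize("g, expected", [(8.0, 4.0), (1.0, 1.0)])
    def test_closed_form(self, g, expected):
        fit = make_fit(2 / 3, 1.0)
        assert fit.predict_t(g) == pytest.approx(expected, rel=1e-12)

    def test_hk97_prediction_consistent_with_structure(self, g2t_fit):
        # HK97: T=7 at 39.7 kbp; the fitted model lands within its own MRE
        assert g2t_fit.predict_t(39.7) == pytest.approx(7.0, rel=0.09)

    def test_rejects_nonpositive_genome(self, g2t_fit):
        with pytest.raises(ValueError):
            g2t_fit.predict_t(-3.0)


class TestErrorCurve:
    def test_noiseless_records_zero_error(self):
        recs = simulate_g2t_records(20, noise_sd=0.0, seed=1)
        table = mre_curve(recs, [5, 10], reps=50, seed=2)
        assert np.allclose(table["mre"], 0.0, atol=1e-10)

    def test_error_decreases_with_training_size(self, highres_records):
        table = mre_curve(highres_records, [5, 30], reps=4000, seed=3)
        m5, m30 = table.set_index("n")["mre"][[5, 30]]
        assert m5 > m30

    def test_fixture_mre_near_nine_percent(self, highres_records):
        table = mre_curve(highres_records, [30], reps=4000, seed=4)
        assert table["mre"].item() == pytest.approx(0.09, abs=0.005)

    def test_seed_reproducibility(self, highres_records):
        t1 = mre_curve(highres_records, [10], reps=100, seed=7)
        t2 = mre_curve(highres_records, [10], reps=100, seed=7)
        assert t1["mre"].item() == t2["mre"].item()

    def test_rejects_oversized_n(self, highres_records):
        with pytest.raises(ValueError):
            mre_curve(highres_records, [37], reps=10, seed=0)


class TestErrorDecay:
    def test_noiseless_parameters_recovered(self):
        n = np.arange(5, 31)
        mre = 0.5 * np.exp(-0.2 * n) + 0.05
        import pandas as pd

        res = fit_error_decay(pd.DataFrame({"n": n, "mre": mre}))
        assert res.p == pytest.approx(0.5, rel=1e-4)
        assert res.q == pytest.approx(0.2, rel=1e-4)
        assert res.w == pytest.approx(0.05, rel=1e-4)
        assert res.r2 == pytest.approx(1.0, abs=1e-8)

    def test_fixture_curve_saturates_near_nine_percent(self, highres_records):
        table = mre_curve(highres_records, range(5, 31), reps=1000, seed=5)
        res = fit_error_decay(table)
        assert res.r2 > 0.95
        assert res.w == pytest.approx(0.09, abs=0.01)
        # extrapolation beyond the data stays at the asymptote
        assert res.predict(100) == pytest.approx(res.w, abs=1e-3)

    def test_bootstrap_ci_contains_point_estimate(self, highres_records):
        table = mre_curve(highres_records, range(5, 31), reps=300, seed=6)
        res = fit_error_decay(table).bootstrap_ci(n_boot=200, seed=7)
        assert res.ci_w[0] <= res.w <= res.ci_w[1]
        assert res.ci_p[0] <= res.p <= res.ci_p[1]

    def test_too_few_points_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            fit_error_decay(pd.DataFrame({"n": [5, 6, 7], "mre": [0.2, 0.1, 0.09]}))


class TestAssignment:
    def test_prediction_on_t7(self):
        fit = make_fit(2 / 3, 1.0)
        # G chosen so T_pred = 7 exactly; 9% margin excludes 16/3 and 28/3
        asg = fit.assign(7.0**1.5, 0.09)
        assert asg.t_predicted == pytest.approx(7.0, rel=1e-12)
        assert [c.t_float for c in asg.candidates] == [7.0]
        assert asg.selected.t_float == 7.0
        assert asg.delta_t == pytest.approx(0.63, abs=1e-9)

    def test_exact_t_with_small_margin(self):
        fit = make_fit(2 / 3, 1.0)
        asg = fit.assign(4.0**1.5, 1e-6)
        assert asg.selected.t_float == 4.0

    def test_gap_yields_elongated(self):
        fit = make_fit(2 / 3, 1.0)
        asg = fit.assign(2.0**1.5, 0.09)  # T_pred = 2: no lattice value near
        assert asg.is_elongated
        assert asg.label == ELONGATED
        assert asg.candidates == []

    def test_dual_lattice_t_gives_one_candidate_per_lattice(self):
        fit = make_fit(2 / 3, 1.0)
        asg = fit.assign(12.0**1.5, 0.01)
        assert sorted(c.lattice for c in asg.candidates) == [
            "hexagonal",
            "trihexagonal",
        ]
        assert asg.selected.lattice == "hexagonal"  # tie-break rule

    def test_invalid_mre(self, g2t_fit):
        with pytest.raises(ValueError):
            g2t_fit.assign(40.0, 1.5)


class TestGenomeRange:
    def test_closed_form_interval(self):
        fit = make_fit(2 / 3, 1.0)
        lo, hi = fit.genome_range(4.0, 0.09)
        assert lo == pytest.approx((4 / 1.09) ** 1.5, rel=1e-12)
        assert hi == pytest.approx((4 / 0.91) ** 1.5, rel=1e-12)
        assert lo < hi

    def test_interval_ordering_always(self, g2t_fit):
        for t in [1, 4, 7, 9.33, 25, 52]:
            lo, hi = g2t_fit.genome_range(t, 0.09)
            assert lo < hi

    def test_mre_ge_one_rejected(self, g2t_fit):
        with pytest.raises(ValueError):
            g2t_fit.genome_range(7, 1.0)


ARCHS = enumerate_architectures(60)


@settings(max_examples=100, deadline=None)
@given(
    g=st.floats(5.0, 600.0),
    t_idx=st.integers(0, len(ARCHS) - 1),
)
def test_assignment_and_range_are_mutually_consistent(g2t_fit, g, t_idx):
    """G lies in genome_range(t) iff t is a candidate of assign(G)."""
    arch = ARCHS[t_idx]
    if arch.t_float < 1:
        return
    mre = 0.09
    lo, hi = g2t_fit.genome_range(arch.t_float, mre)
    in_range = lo <= g <= hi
    candidates = {c.t_float for c in g2t_fit.assign(g, mre).candidates}
    # guard against float boundary coincidences
    t_pred = g2t_fit.predict_t(g)
    boundary = min(
        abs(arch.t_float - t_pred * (1 - mre)), abs(arch.t_float - t_pred * (1 + mre))
    )
    if boundary < 1e-9 * arch.t_float:
        return
    assert in_range == (arch.t_float in candidates)


def test_theoretical_exponent_is_two_thirds():
    assert theoretical_exponent() == pytest.approx(2 / 3, abs=1e-12)
    assert round(theoretical_exponent(), 2) == 0.67
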