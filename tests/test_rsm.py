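import numpy as np
import pytest

from medreba import datasets as ds
from medreba.errors import BoundsError, FitError
from medreba.reba_core import Adjustments
from medreba.rsm import (DEFAULT_FACTORS, Design, FactorSpec, REFERENCE_MODEL,
                         bbd_design, desirability, fit_linear,
                         optimize_desirability, predict, score_design)


class TestFactorSpec:
    def test_defaults_span_seated_cohort(self):
        pts = [e.points for e in ds.DENTIST_COHORT
               if e.subject in ds.SEATED_IDS]
        lows = (min(p.neck for p in pts), min(p.trunk for p in pts),
                min(p.upper_arm for p in pts), min(p.lower_arm for p in pts))
        highs = (max(p.neck for p in pts), max(p.trunk for p in pts),
                 max(p.upper_arm for p in pts), max(p.lower_arm for p in pts))
        assert DEFAULT_FACTORS.low == lows == (2, 3, 3, 1)
        assert DEFAULT_FACTORS.high == highs == (3, 5, 6, 2)

    def test_low_ge_high_rejected(self):
        with pytest.raises(BoundsError):
            FactorSpec(low=(2, 3, 3, 1), high=(2, 5, 6, 2))

    def test_wrong_arity_rejected(self):
        with pytest.raises(BoundsError):
            FactorSpec(low=(1, 2, 3), high=(2, 3, 4))


class TestBBDesign:
    def test_28_runs_with_four_center_replicates(self):
        assert len(bbd_design(center_replicates=4)) == 28

    def test_24_edge_runs_without_centers(self):
        design = bbd_design(center_replicates=0)
        assert len(design) == 24
        assert not any((row == 0).all() for row in design.coded)

    def test_every_edge_run_has_exactly_two_nonzero_codes(self):
        design = bbd_design(center_replicates=4)
        nonzero = (design.coded != 0).sum(axis=1)
        assert sorted(nonzero) == [0] * 4 + [2] * 24

    def test_all_pairs_covered(self):
        design = bbd_design(center_replicates=0)
        seen = {tuple(np.nonzero(row)[0]) for row in design.coded}
        assert len(seen) == 6

    def test_natural_decoding(self):
        design = bbd_design(center_replicates=1)
        center = design.natural[-1]
        assert tuple(center) == (2.5, 4.0, 4.5, 1.5)
        assert design.natural.min(axis=0).tolist() == [2, 3, 3, 1]
        assert design.natural.max(axis=0).tolist() == [3, 5, 6, 2]


class TestScoreDesign:
    def test_verification_profiles(self):
        d = Design(coded=np.zeros((2, 4)),
                   natural=np.array([[2, 3, 3, 1], [3, 5, 4, 1]], float))
        scored = score_design(d, legs=1, wrist=2)
        assert scored.responses.tolist() == [7.0, 11.0]

    def test_consistent_with_direct_chart_call(self):
        from medreba.reba_core import RebaPoints, reba_total
        corner = np.array([[2, 3, 3, 1]], float)  # all-low corner
        scored = score_design(Design(coded=np.zeros((1, 4)), natural=corner))
        direct = reba_total(RebaPoints(2, 3, 1, 3, 1, 2)).total
        assert scored.responses[0] == direct

    def test_half_up_midpoints(self):
        d = Design(coded=np.zeros((1, 4)),
                   natural=np.array([[2.5, 4.0, 4.5, 1.5]]))
        scored = score_design(d)
        from medreba.reba_core import RebaPoints, reba_total
        assert scored.responses[0] == reba_total(
            RebaPoints(3, 4, 1, 5, 2, 2)).total


class TestFitLinear:
    def test_exact_interpolation_of_linear_rule(self, rng):
        design = bbd_design(center_replicates=4)
        beta = np.array([0.7, 1.1, 0.4, 0.9])
        y = 2.0 + design.natural @ beta
        model = fit_linear(Design(coded=design.coded, natural=design.natural,
                                  responses=y))
        assert model.intercept == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(list(model.coefficients.values()), beta, atol=1e-9)
        assert model.r2 == pytest.approx(1.0)

    def test_column_permutation_permutes_coefficients(self, rng):
        design = bbd_design(center_replicates=4)
        y = 1.0 + design.natural @ [0.5, 1.5, 2.5, 3.5] + \
            rng.normal(0, 0.1, 28)
        m1 = fit_linear(Design(design.coded, design.natural, y))
        perm = [2, 0, 3, 1]
        m2 = fit_linear(Design(design.coded[:, perm],
                               design.natural[:, perm], y))
        vals1 = list(m1.coefficients.values())
        vals2 = list(m2.coefficients.values())
        assert np.allclose(vals2, [vals1[i] for i in perm], atol=1e-9)

    def test_chart_scored_design_positive_coefficients(self):
        model = fit_linear(score_design(bbd_design()))
        assert all(v > 0 for v in model.coefficients.values())
        assert model.anova["model"]["p"] < 0.05

    def test_r2_ordering_on_chart_design(self):
        # PRESS-predicted <= adjusted <= plain R2
        for adj in (Adjustments(1, 1, 1), Adjustments(0, 0, 0)):
            model = fit_linear(score_design(bbd_design(), adj=adj))
            assert model.predicted_r2 <= model.adjusted_r2 <= model.r2

    def test_bare_chart_fit_quality(self):
        # table lookups without load/coupling/activity modifiers
        model = fit_linear(score_design(bbd_design(), adj=Adjustments(0, 0, 0)))
        assert model.adjusted_r2 >= 0.8
        assert model.anova["model"]["p"] < 0.05

    def test_per_term_anova_reported(self):
        model = fit_linear(score_design(bbd_design(), adj=Adjustments(0, 0, 0)))
        for term in ("neck", "trunk", "upper_arm", "lower_arm"):
            assert model.anova[term]["F"] > 0
            assert 0.0 <= model.anova[term]["p"] < 1.0
        # the dominant factors are individually significant
        assert model.anova["trunk"]["p"] < 0.001
        assert model.anova["upper_arm"]["p"] < 0.001

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 4))
        with pytest.raises(FitError):
            fit_linear(Design(coded=X, natural=X, responses=np.arange(10.0)))

    def test_too_few_runs_rejected(self):
        with pytest.raises(FitError):
            fit_linear(Design(coded=np.zeros((4, 4)),
                              natural=np.zeros((4, 4)),
                              responses=np.zeros(4)))


class TestPredict:
    def test_reference_model_at_minimization_solution(self):
        assert round(predict(REFERENCE_MODEL, (2, 3, 3, 1)), 1) == 7.2

    def test_reference_model_rounded_profile(self):
        assert predict(REFERENCE_MODEL, (2, 3, 4, 1), rounded=True) == 8

    def test_intercept_at_origin(self):
        assert predict(REFERENCE_MODEL, (0, 0, 0, 0)) == pytest.approx(
            ds.REFERENCE_MODEL_COEFFS["intercept"])

    def test_printed_maximization_levels(self):
        levels = ds.OPTIMIZATION_VERIFICATION["maximize"]["continuous"]
        assert predict(REFERENCE_MODEL, levels) == pytest.approx(11.11, abs=0.02)

    def test_nonfinite_rejected(self):
        with pytest.raises(BoundsError):
            predict(REFERENCE_MODEL, (1, 2, float("nan"), 4))


class TestDesirability:
    def test_maximize_at_high_bound(self):
        assert desirability(12.0, "maximize", 9.0, 12.0) == 1.0

    def test_minimize_ramp(self):
        assert desirability(10.5, "minimize", 9.0, 12.0) == pytest.approx(0.5)

    def test_clipping(self):
        assert desirability(20.0, "maximize", 9.0, 12.0) == 1.0
        assert desirability(5.0, "maximize", 9.0, 12.0) == 0.0

    def test_bad_bounds(self):
        with pytest.raises(BoundsError):
            desirability(1.0, "maximize", 2.0, 2.0)


class TestOptimizeDesirability:
    def test_minimize_reaches_all_low_corner(self):
        result = optimize_desirability(REFERENCE_MODEL, goal="minimize",
                                       response_bounds=(9.0, 12.0),
                                       starts=30, seed=0)
        levels, pred, d = result.solutions[0]
        assert levels == (2.0, 3.0, 3.0, 1.0)
        assert round(pred, 1) == 7.2
        assert 0.0 <= d <= 1.0

    def test_maximize_positive_model_reaches_all_high_corner(self):
        result = optimize_desirability(REFERENCE_MODEL, goal="maximize",
                                       response_bounds=(9.0, 12.0),
                                       starts=30, seed=0)
        assert result.solutions[0][0] == (3.0, 5.0, 6.0, 2.0)

    def test_seed_reproducibility(self):
        kw = dict(goal="minimize", response_bounds=(9.0, 12.0), starts=25)
        r1 = optimize_desirability(REFERENCE_MODEL, seed=42, **kw)
        r2 = optimize_desirability(REFERENCE_MODEL, seed=42, **kw)
        assert r1.solutions == r2.solutions

    def test_default_bounds_from_design(self):
        design = score_design(bbd_design())
        result = optimize_desirability(REFERENCE_MODEL, goal="minimize",
                                       design=design, starts=10, seed=1)
        assert result.solutions[0][0] == (2.0, 3.0, 3.0, 1.0)

    def test_desirability_sorted_and_bounded(self):
        result = optimize_desirability(REFERENCE_MODEL, goal="minimize",
                                       response_bounds=(9.0, 12.0),
                                       starts=40, seed=3)
        ds_vals = [s[2] for s in result.solutions]
        assert all(0.0 <= d <= 1.0 for d in ds_vals)
        assert ds_vals == sorted(ds_vals, reverse=True)

    def test_bad_bounds_rejected(self):
        with pytest.raises(BoundsError):
            optimize_desirability(REFERENCE_MODEL, goal="minimize",
                                  response_bounds=(5.0, 5.0))
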