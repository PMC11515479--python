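"""Huber IRLS regression and iterative residual-correlation selection."""

import numpy as np
import pytest

from paco2est import (CandidateDescriptor, FORCED_TERM, FitConfig,
                      apply_filters, build_design_matrix,
                      enumerate_candidates, fit_huber, huber_weights, pearson,
                      published_model, robust_scale, select_iteratively)
from paco2est.features import DesignMatrix
from paco2est.errors import (DegenerateScaleError, DomainError,
                             InsufficientDataError, SingularDesignError)


def make_design(X: np.ndarray, y: np.ndarray,
                names: list[str] | None = None) -> DesignMatrix:
    names = names or [f"c{i}" for i in range(X.shape[1])]
    return DesignMatrix(X=X, y=y,
                        descriptors=[CandidateDescriptor(n, "identity")
                                     for n in names],
                        sample_ids=[str(i) for i in range(len(y))])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson(np.array([1.0, 2.0, 3.0]),
                       np.array([1.0, 2.0, 4.0])) == pytest.approx(0.9820,
                                                                   abs=5e-5)

    def test_constant_input_undefined(self):
        assert np.isnan(pearson(np.ones(5), np.arange(5.0)))

    def test_preconditions(self):
        with pytest.raises(DomainError):
            pearson(np.arange(3.0), np.arange(4.0))
        with pytest.raises(InsufficientDataError):
            pearson(np.arange(2.0), np.arange(2.0))


class TestHuberWeights:
    def test_inside_and_outside_the_elbow(self):
        w = huber_weights(np.array([0.0, 1.345, 2.69]), scale=1.0, k=1.345)
        assert w[0] == 1.0
        assert w[1] == 1.0
        assert w[2] == pytest.approx(0.5)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(DegenerateScaleError):
            huber_weights(np.array([1.0]), scale=0.0)


class TestRobustScale:
    def test_mad_of_symmetric_triplet(self):
        assert robust_scale(np.array([-1.0, 0.0, 1.0])) == pytest.approx(1.4826)

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            robust_scale(np.full(5, 3.0))

    def test_majority_at_median_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            robust_scale(np.array([0.0, 0.0, 0.0, 10.0]))


class TestFitHuber:
    def test_exact_linear_data_recovered_quickly(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-5, 5, size=(20, 2))
        y = 3.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        model = fit_huber(make_design(X, y))
        assert model.intercept == pytest.approx(3.0, abs=1e-9)
        coefs = list(model.coefficients.values())
        assert coefs == pytest.approx([2.0, -0.5], abs=1e-9)
        assert model.converged and model.n_iter <= 3

    def test_huber_resists_gross_outlier_better_than_ols(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 20)
        y = 2.0 * x
        y[7] += 100.0
        model = fit_huber(make_design(x[:, None], y))
        # closed-form least-squares oracle on the same data
        ols_slope = np.polyfit(x, y, 1)[0]
        huber_slope = list(model.coefficients.values())[0]
        assert abs(huber_slope - 2.0) < abs(ols_slope - 2.0)

    def test_duplicated_column_is_singular(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        X = np.column_stack([x, x])
        with pytest.raises(SingularDesignError):
            fit_huber(make_design(X, rng.normal(size=10)))

    def test_large_k_reduces_to_least_squares(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            X = rng.normal(size=(30, 3))
            y = rng.normal(size=30)
            model = fit_huber(make_design(X, y), FitConfig(huber_k=1e9))
            A = np.column_stack([np.ones(30), X])
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            got = np.array([model.intercept, *model.coefficients.values()])
            assert np.allclose(got, beta, atol=1e-9)

    def test_matches_statsmodels_rlm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = rng.uniform(-3, 3, size=(200, 2))
        y = 1.0 + 0.5 * X[:, 0] - 2.0 * X[:, 1] + rng.normal(0, 1, 200)
        y[:10] += 15.0
        model = fit_huber(make_design(X, y))
        rlm = sm.RLM(y, sm.add_constant(X),
                     M=sm.robust.norms.HuberT(t=1.345)).fit(scale_est="mad")
        got = np.array([model.intercept, *model.coefficients.values()])
        # statsmodels centres its MAD at zero rather than at the residual
        # median, so agreement is close but not exact
        assert np.allclose(got, rlm.params, atol=2e-3)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_huber(make_design(np.ones((3, 2)), np.ones(3)))


class TestSelection:
    def test_noise_free_recovery_of_published_terms(self, noisefree_design):
        kept, _ = apply_filters(noisefree_design)
        catalogue = enumerate_candidates(kept)
        design = build_design_matrix(kept, [FORCED_TERM, *catalogue])
        model, trace = select_iteratively(design)
        expected = {CandidateDescriptor("O2diff", "square"),
                    CandidateDescriptor("%Spont", "identity"),
                    CandidateDescriptor("Pmean", "cube"),
                    CandidateDescriptor("Vte", "log")}
        assert {s.chosen for s in trace.steps} == expected
        truth = published_model()
        assert model.intercept == pytest.approx(truth.intercept, abs=1e-6)
        for term, coef in truth.coefficients.items():
            assert model.coefficients[term] == pytest.approx(coef, abs=1e-6)
        assert trace.stop_reason == "threshold"

    def test_independent_noise_candidates_never_selected(self):
        rng = np.random.default_rng(6)
        n = 5000
        etco2 = rng.uniform(20, 70, n)
        y = 30.0 + 0.9 * etco2
        X = np.column_stack([etco2] + [rng.normal(size=n) for _ in range(8)])
        design = DesignMatrix(
            X=X, y=y,
            descriptors=[FORCED_TERM] + [CandidateDescriptor(f"noise{i}",
                                                             "identity")
                                         for i in range(8)],
            sample_ids=[str(i) for i in range(n)])
        model, trace = select_iteratively(design)
        assert trace.steps == []
        assert set(model.coefficients) == {FORCED_TERM}
        assert model.intercept == pytest.approx(30.0, abs=1e-6)

    def test_threshold_one_selects_nothing(self, noisefree_design):
        kept, _ = apply_filters(noisefree_design[:200])
        catalogue = enumerate_candidates(kept)
        design = build_design_matrix(kept, [FORCED_TERM, *catalogue])
        _, trace = select_iteratively(design, FitConfig(corr_threshold=1.0))
        assert trace.steps == [] and trace.stop_reason == "threshold"

    def test_max_terms_cap_reported(self, noisefree_design):
        kept, _ = apply_filters(noisefree_design)
        catalogue = enumerate_candidates(kept)
        design = build_design_matrix(kept, [FORCED_TERM, *catalogue])
        cfg = FitConfig(corr_threshold=0.01, max_terms=2)
        _, trace = select_iteratively(design, cfg)
        assert len(trace.steps) == 2 and trace.stop_reason == "max_terms"

    def test_tie_breaks_to_earlier_catalogue_position(self):
        rng = np.random.default_rng(7)
        n = 100
        etco2 = rng.uniform(20, 70, n)
        z = rng.normal(size=n)
        y = 10.0 + etco2 + 5.0 * z
        X = np.column_stack([etco2, z, z])       # exact duplicate candidate
        design = DesignMatrix(
            X=X, y=y,
            descriptors=[FORCED_TERM,
                         CandidateDescriptor("first", "identity"),
                         CandidateDescriptor("second", "identity")],
            sample_ids=[str(i) for i in range(n)])
        _, trace = select_iteratively(design)
        assert trace.steps[0].chosen == CandidateDescriptor("first", "identity")

    def test_term_sets_grow_and_correlations_exceed_threshold(self,
                                                              noisefree_design):
        kept, _ = apply_filters(noisefree_design)
        catalogue = enumerate_candidates(kept)
        design = build_design_matrix(kept, [FORCED_TERM, *catalogue])
        cfg = FitConfig()
        _, trace = select_iteratively(design, cfg)
        sizes = [len(s.model.coefficients) for s in trace.steps]
        assert sizes == sorted(set(sizes))
        assert all(s.max_abs_r > cfg.corr_threshold for s in trace.steps)
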