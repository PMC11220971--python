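"""Latent class mixed model likelihood, classification and fit indices."""

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import multivariate_normal, norm

from crtraj.cohort import LongitudinalCohort
from crtraj.lcmm import (
    FitControl,
    LikelihoodEngine,
    ModelSpec,
    ParameterVector,
    bic,
    class_probabilities,
    count_free_params,
    default_init,
    fit,
    permute_classes,
    posterior_matrix,
    refit,
    relative_entropy,
    sabic,
    subject_loglik,
    total_loglik,
)
from crtraj.links import build_link, link_transform

IDENTITY = build_link("linear")


def _pv(xi, beta, delta, chol, sigma, omega=None):
    return ParameterVector(np.asarray(xi, float), np.asarray(beta, float),
                           np.asarray(delta, float), np.asarray(chol, float),
                           sigma, np.array([0.0, 1.0]), omega)


# ---------------------------------------------------------------------------
# class probabilities
# ---------------------------------------------------------------------------


class TestClassProbabilities:
    def test_symmetric_two_class(self):
        np.testing.assert_allclose(class_probabilities([0.0]), [0.5, 0.5])

    def test_single_class(self):
        np.testing.assert_allclose(class_probabilities([]), [1.0])

    def test_three_class_softmax_arithmetic(self):
        # pi_g = exp(xi_g) / (exp(1) + exp(0.5) + exp(0))
        e = np.exp([1.0, 0.5, 0.0])
        np.testing.assert_allclose(class_probabilities([1.0, 0.5]), e / e.sum(), rtol=1e-12)

    def test_sums_to_one_and_positive(self):
        p = class_probabilities([10.0, -10.0, 3.0])
        assert np.isclose(p.sum(), 1.0) and np.all(p > 0)


# ---------------------------------------------------------------------------
# subject- and cohort-level likelihood
# ---------------------------------------------------------------------------


class TestSubjectLoglik:
    spec = ModelSpec(1, IDENTITY, shared_design=(), random_design=("intercept",))

    def test_single_visit_standard_normal(self):
        pv = _pv([], [], [[0.0, 0.0]], [[0.0]], 1.0)
        df = pd.DataFrame({"time": [0.0], "outcome": [0.0]})
        assert subject_loglik(df, self.spec, pv) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_two_visits_matches_bivariate_normal(self):
        # random-intercept variance 0.5, residual variance 0.25
        pv = _pv([], [], [[0.0, 0.0]], [[np.sqrt(0.5)]], 0.5)
        df = pd.DataFrame({"time": [0.0, 1.0], "outcome": [0.2, 0.1]})
        oracle = multivariate_normal.logpdf([0.2, 0.1], cov=[[0.75, 0.5], [0.5, 0.75]])
        assert subject_loglik(df, self.spec, pv) == pytest.approx(oracle, abs=1e-12)

    def test_two_class_mixture_matches_gauss_hermite(self):
        """Closed-form random-effect integration vs brute-force quadrature."""
        spec = ModelSpec(2, IDENTITY, shared_design=())
        chol = np.array([[0.6, 0.0], [0.1, 0.2]])
        pv = _pv([0.4], [], [[0.0, -0.1], [1.0, -0.5]], chol, 0.5)
        pi = class_probabilities(pv.xi)
        df = pd.DataFrame({"time": [0.0, 0.8, 1.7], "outcome": [0.3, -0.2, 0.4]})
        t = df["time"].to_numpy()
        y = df["outcome"].to_numpy()
        nodes, weights = hermegauss(60)  # weights for standard-normal kernel
        weights = weights / np.sqrt(2 * np.pi)
        total = 0.0
        Z = np.column_stack([np.ones_like(t), t])
        for g in range(2):
            mu = pv.delta[g, 0] + pv.delta[g, 1] * t
            val = 0.0
            for i, u1 in enumerate(nodes):
                for j, u2 in enumerate(nodes):
                    b = chol @ np.array([u1, u2])
                    dens = np.prod(norm.pdf(y, mu + Z @ b, 0.5))
                    val += weights[i] * weights[j] * dens
            total += pi[g] * val
        assert subject_loglik(df, spec, pv) == pytest.approx(np.log(total), abs=1e-6)


class TestTotalLoglik:
    spec = ModelSpec(1, IDENTITY, shared_design=())

    def test_single_subject_equals_subject_loglik(self, tiny_cohort):
        pv = _pv([], [], [[0.0, 0.0]], np.eye(2) * 0.3, 0.7)
        sub = tiny_cohort.subset(["a"])
        df = sub.visits
        assert total_loglik(sub, self.spec, pv) == pytest.approx(
            subject_loglik(df, self.spec, pv))

    def test_additivity_over_subjects(self, tiny_cohort):
        pv = _pv([], [], [[0.0, 0.0]], np.eye(2) * 0.3, 0.7)
        parts = sum(subject_loglik(tiny_cohort.subject_table(s), self.spec, pv)
                    for s in tiny_cohort.subject_ids)
        assert total_loglik(tiny_cohort, self.spec, pv) == pytest.approx(parts, abs=1e-10)

    def test_duplicated_subject_doubles_contribution(self):
        visits = pd.DataFrame({"subject_id": ["a"] * 2 + ["a2"] * 2,
                               "time": [0.0, 1.0] * 2,
                               "outcome": [0.2, -0.1] * 2})
        base = pd.DataFrame(index=pd.Index(["a", "a2"], name="subject_id"))
        cohort = LongitudinalCohort(visits, base, covariate_columns=())
        pv = _pv([], [], [[0.1, -0.2]], np.eye(2) * 0.4, 0.6)
        single = subject_loglik(visits.iloc[:2], self.spec, pv)
        assert total_loglik(cohort, self.spec, pv) == pytest.approx(2 * single, abs=1e-10)

    def test_label_permutation_invariance(self, tiny_cohort):
        spec = ModelSpec(3, IDENTITY, shared_design=())
        pv = _pv([0.5, -0.3], [], [[0.0, 0.0], [1.0, -0.3], [-1.0, 0.2]],
                 np.diag([0.4, 0.1]), 0.5)
        base = total_loglik(tiny_cohort, spec, pv)
        for perm in ([2, 0, 1], [1, 0, 2], [2, 1, 0]):
            assert total_loglik(tiny_cohort, spec, permute_classes(pv, perm)) == \
                pytest.approx(base, abs=1e-10)

    def test_jacobian_bookkeeping_consistency(self, small_cohort):
        """Loglik on raw outcomes = loglik on pre-transformed outcomes + sum log h'."""
        cohort, _ = small_cohort
        link = build_link("splines_equidistant", 5, cohort.outcomes())
        spec = ModelSpec(1, link, shared_design=())
        pv = ParameterVector([], [], [[0.0, -0.05]], np.diag([0.5, 0.05]), 1.0, link.eta)
        h, hp = link_transform(cohort.outcomes(), link)
        transformed = LongitudinalCohort(cohort.visits.assign(outcome=h),
                                         cohort.baseline, covariate_columns=())
        ident_spec = ModelSpec(1, IDENTITY, shared_design=())
        pv_ident = _pv([], [], pv.delta, pv.b_chol, 1.0)
        lhs = total_loglik(cohort, spec, pv)
        rhs = total_loglik(transformed, ident_spec, pv_ident) + np.log(hp).sum()
        assert lhs == pytest.approx(rhs, abs=1e-8)


# ---------------------------------------------------------------------------
# posterior classification
# ---------------------------------------------------------------------------


class TestPosterior:
    def test_single_class_all_ones(self, fitted_g1, small_cohort):
        cohort, _ = small_cohort
        post = posterior_matrix(fitted_g1, cohort)
        np.testing.assert_allclose(post, 1.0)

    def test_identical_classes_are_uniform(self, tiny_cohort):
        spec = ModelSpec(2, IDENTITY, shared_design=())
        pv = _pv([0.0], [], [[0.2, -0.1], [0.2, -0.1]], np.diag([0.4, 0.1]), 0.5)
        post = posterior_matrix(pv, tiny_cohort, spec)
        np.testing.assert_allclose(post, 0.5, atol=1e-12)

    def test_bayes_rule_oracle(self, tiny_cohort):
        spec = ModelSpec(2, IDENTITY, shared_design=())
        pv = _pv([0.7], [], [[0.0, 0.0], [0.8, -0.4]], np.diag([0.4, 0.1]), 0.5)
        post = posterior_matrix(pv, tiny_cohort, spec)
        pi = class_probabilities(pv.xi)
        for i, sid in enumerate(tiny_cohort.subject_ids):
            df = tiny_cohort.subject_table(sid)
            lls = []
            for g in range(2):
                one = ModelSpec(1, IDENTITY, shared_design=())
                pvg = _pv([], [], [pv.delta[g]], pv.b_chol, pv.sigma_eps)
                lls.append(subject_loglik(df, one, pvg))
            w = pi * np.exp(lls)
            np.testing.assert_allclose(post[i], w / w.sum(), atol=1e-10)

    def test_rows_sum_to_one(self, tiny_cohort):
        spec = ModelSpec(3, IDENTITY, shared_design=())
        pv = _pv([2.0, -1.0], [], [[0.0, 0.0], [1.0, -0.3], [-1.0, 0.2]],
                 np.diag([0.4, 0.1]), 0.5)
        post = posterior_matrix(pv, tiny_cohort, spec)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


class TestFitIndices:
    def test_relative_entropy_examples(self):
        assert relative_entropy(np.array([[1.0, 0.0], [0.0, 1.0]])) == 1.0
        assert relative_entropy(np.full((4, 3), 1 / 3)) == pytest.approx(0.0, abs=1e-12)
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        hand = 1.0 - (0.32508 + 0.50040) / (2 * np.log(2))
        assert relative_entropy(post) == pytest.approx(hand, abs=1e-4)

    def test_relative_entropy_undefined_for_one_class(self):
        with pytest.raises(ValueError):
            relative_entropy(np.ones((5, 1)))

    def test_sabic_formula(self):
        assert sabic(-100.0, 10, 200) == pytest.approx(200 + 10 * np.log(202 / 24))

    def test_sabic_zero_penalty_at_n22(self):
        assert sabic(-123.4, 17, 22) == pytest.approx(2 * 123.4)

    def test_sabic_below_bic_above_n22(self):
        for n in (23, 100, 1000):
            assert sabic(-50.0, 5, n) < bic(-50.0, 5, n)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _balanced_cohort(seed=0, n=80):
    rng = np.random.default_rng(seed)
    times = np.array([0.0, 1.0, 2.0, 3.0])
    rows, base = [], []
    for i in range(n):
        age, sex = rng.normal(72, 8), float(rng.random() < 0.6)
        b0, b1 = rng.normal(0, 0.4), rng.normal(0, 0.05)
        y = 0.3 - 0.1 * times + 0.02 * (age - 72) + 0.3 * sex + b0 + b1 * times \
            + rng.normal(0, 0.3, len(times))
        for t, yy in zip(times, y):
            rows.append((f"s{i}", t, yy))
        base.append((f"s{i}", age, sex))
    visits = pd.DataFrame(rows, columns=["subject_id", "time", "outcome"])
    baseline = pd.DataFrame(base, columns=["subject_id", "baseline_age", "sex"]).set_index("subject_id")
    return LongitudinalCohort(visits, baseline, covariate_columns=("baseline_age", "sex"))


class TestFit:
    def test_g1_fixed_effects_match_gls_solve(self):
        """At the ML optimum the fixed effects equal the GLS solution given
        the fitted variance components (ordinary linear mixed model)."""
        cohort = _balanced_cohort()
        spec = ModelSpec(1, IDENTITY, shared_design=("baseline_age", "sex"))
        fm = fit(cohort, spec)
        assert fm.converged
        pv = fm.params
        V = None
        XtVX = np.zeros((4, 4))
        XtVy = np.zeros(4)
        scaling = fm.covariate_scaling
        for sid in cohort.subject_ids:
            df = cohort.subject_table(sid)
            t = df["time"].to_numpy()
            y = df["outcome"].to_numpy()
            age = cohort.baseline.loc[sid, "baseline_age"]
            sex = cohort.baseline.loc[sid, "sex"]
            if "baseline_age" in scaling:
                mu, sd = scaling["baseline_age"]
                age = (age - mu) / sd
            X = np.column_stack([np.full_like(t, age), np.full_like(t, sex),
                                 np.ones_like(t), t])
            Z = np.column_stack([np.ones_like(t), t])
            V = Z @ pv.B @ Z.T + pv.sigma_eps**2 * np.eye(len(t))
            Vi = np.linalg.inv(V)
            XtVX += X.T @ Vi @ X
            XtVy += X.T @ Vi @ y
        gls = np.linalg.solve(XtVX, XtVy)
        fitted = np.concatenate([pv.beta, pv.delta[0]])
        np.testing.assert_allclose(fitted, gls, atol=1e-4)

    def test_g1_matches_statsmodels_mixedlm(self):
        """Independent cross-check against a dedicated LMM implementation."""
        import statsmodels.api as sm

        cohort = _balanced_cohort(seed=5)
        spec = ModelSpec(1, IDENTITY, shared_design=("baseline_age", "sex"))
        fm = fit(cohort, spec, scale_covariates=False)
        vis = cohort.visits.merge(cohort.baseline.reset_index(), on="subject_id")
        X = sm.add_constant(vis[["time", "baseline_age", "sex"]])
        md = sm.MixedLM(vis["outcome"], X, groups=vis["subject_id"],
                        exog_re=sm.add_constant(vis[["time"]]))
        res = md.fit(reml=False, method="lbfgs", maxiter=500, disp=False)
        ours = {"const": fm.params.delta[0, 0], "time": fm.params.delta[0, 1],
                "baseline_age": fm.params.beta[0], "sex": fm.params.beta[1]}
        for name, val in ours.items():
            assert val == pytest.approx(res.params[name], abs=2e-3)
        assert fm.loglik == pytest.approx(res.llf, abs=1e-2)

    def test_refit_is_fixed_point(self, fitted_g1, small_cohort):
        cohort, _ = small_cohort
        again = refit(cohort, fitted_g1)
        assert again.loglik == pytest.approx(fitted_g1.loglik, abs=1e-3)

    def test_fit_never_worse_than_start(self, small_cohort):
        cohort, _ = small_cohort
        spec = ModelSpec(2, IDENTITY)
        engine = LikelihoodEngine(cohort, spec, scale_covariates=True)
        init = default_init(cohort, spec, engine)
        ll0 = engine.total_loglik(init)
        fm = fit(cohort, spec, init=init)
        assert fm.loglik >= ll0 - 1e-6

    def test_nonconvergence_is_flagged_not_raised(self, small_cohort):
        cohort, _ = small_cohort
        spec = ModelSpec(2, IDENTITY)
        fm = fit(cohort, spec, control=FitControl(max_iter=2))
        assert fm.converged is False

    def test_npar_counting(self):
        # linear link, G=3, 5 shared covariates: 2 xi + 5 beta + 6 delta
        # + 3 chol + 1 sigma = 17
        spec = ModelSpec(3, IDENTITY)
        assert count_free_params(spec) == 17
        # 5-knot spline: sigma fixed, first intercept fixed, 7 eta free
        link = build_link("splines_equidistant", 5, np.linspace(-2, 2, 30))
        spec2 = ModelSpec(3, link)
        assert count_free_params(spec2) == 2 + 5 + 5 + 3 + 7

    def test_posterior_and_indices_populated(self, fitted_g1, small_cohort):
        cohort, _ = small_cohort
        fm = fitted_g1
        assert fm.posterior.shape == (cohort.n_subjects, 1)
        assert fm.relative_entropy is None
        assert fm.sabic == pytest.approx(sabic(fm.loglik, fm.npar, cohort.n_subjects))
        assert fm.bic == pytest.approx(bic(fm.loglik, fm.npar, cohort.n_subjects))
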