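"""Likelihood, estimation and classification for latent class mixed models.

The model: subject ``i`` belongs to latent class ``g`` with probability
``pi_g = softmax(xi)_g`` (intercept-only multinomial logit, last class as
reference).  Conditional on class, the link-transformed outcome follows a
linear mixed model,

    h(y_ij) = x_i' beta + u_ij' delta_g + z_ij' b_i + eps_ij,

with class-common covariate effects ``beta``, class-specific intercept and
slope ``delta_g``, subject random effects ``b_i ~ N(0, B)`` (optionally
scaled per class by ``omega_g``) and residual ``eps ~ N(0, sigma_eps^2)``.
Because the structure is linear-Gaussian, random effects integrate out in
closed form: the subject contribution is a mixture of multivariate-normal
densities plus the link Jacobian ``sum_j log h'(y_ij)``.

Identifiability: when the link is estimated (spline/beta families) the
residual SD is fixed at 1 and the first class' latent intercept at 0, the
link carrying location and scale; for the linear link the link is fixed to
the identity and intercepts and ``sigma_eps`` are free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .cohort import DEFAULT_COVARIATES, LongitudinalCohort
from .links import SPLINE_FAMILIES, LinkSpec, ispline_design, link_transform

_LOG_2PI = float(np.log(2.0 * np.pi))


class NumericalError(RuntimeError):
    """A likelihood evaluation failed for numerical reasons (e.g. non-PSD covariance)."""


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Structure of one candidate latent class mixed model."""

    n_classes: int
    link: LinkSpec
    shared_design: tuple[str, ...] = DEFAULT_COVARIATES
    class_design: tuple[str, ...] = ("intercept", "time")
    random_design: tuple[str, ...] = ("intercept", "time")
    class_variance_scaling: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not self.class_design:
            raise ValueError("class_design must be non-empty")
        bad = set(self.random_design) - {"intercept", "time"}
        if bad:
            raise ValueError(f"random_design limited to intercept/time, got {sorted(bad)}")
        self.shared_design = tuple(self.shared_design)
        self.class_design = tuple(self.class_design)
        self.random_design = tuple(self.random_design)

    @property
    def n_shared(self) -> int:
        return len(self.shared_design)

    @property
    def n_class_coef(self) -> int:
        return len(self.class_design)

    @property
    def n_random(self) -> int:
        return len(self.random_design)


@dataclass
class ParameterVector:
    """All model parameters on their natural scale.

    ``b_chol`` is a lower-triangular factor so ``B = b_chol @ b_chol.T`` is
    positive semidefinite by construction.  ``omega`` holds the G-1 free
    class variance scalings (last class fixed at 1) when enabled.
    """

    xi: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    b_chol: np.ndarray
    sigma_eps: float
    eta: np.ndarray
    omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xi = np.atleast_1d(np.asarray(self.xi, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        self.b_chol = np.atleast_2d(np.asarray(self.b_chol, dtype=float))
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        if self.omega is not None:
            self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be > 0")

    @property
    def B(self) -> np.ndarray:
        return self.b_chol @ self.b_chol.T

    @property
    def n_classes(self) -> int:
        return self.delta.shape[0]

    def copy(self) -> "ParameterVector":
        return ParameterVector(
            self.xi.copy(), self.beta.copy(), self.delta.copy(), self.b_chol.copy(),
            float(self.sigma_eps), self.eta.copy(),
            None if self.omega is None else self.omega.copy(),
        )


def class_probabilities(xi) -> np.ndarray:
    """Class mixing proportions from the G-1 membership logits (last class reference).

    ``pi_g = exp(xi_g) / sum_h exp(xi_h)`` with ``xi_G = 0``; always sums to 1.
    """
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    full = np.concatenate([xi, [0.0]])
    full = full - full.max()
    e = np.exp(full)
    return e / e.sum()


def permute_classes(params: ParameterVector, perm) -> ParameterVector:
    """Relabel classes by ``perm`` (new class g = old class perm[g]); loglik-invariant."""
    perm = np.asarray(perm, dtype=int)
    pi = class_probabilities(params.xi)[perm]
    xi = np.log(pi[:-1]) - np.log(pi[-1])
    out = params.copy()
    out.xi = xi
    out.delta = params.delta[perm].copy()
    if params.omega is not None:
        om = np.concatenate([params.omega, [1.0]])[perm]
        out.omega = om[:-1] / om[-1]
    return out


# ---------------------------------------------------------------------------
# free-parameter layout (optimizer packing)
# ---------------------------------------------------------------------------


class ParameterLayout:
    """Maps between :class:`ParameterVector` and the unconstrained optimizer vector.

    Free parameters: xi (G-1); beta (p); delta (G*q, minus the first class'
    intercept when the link is estimated); the lower triangle of b_chol;
    log sigma_eps (linear link only); link eta (spline/beta only); log omega
    (G-1) when class variance scaling is on.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        G, p, q, r = spec.n_classes, spec.n_shared, spec.n_class_coef, spec.n_random
        self.fix_first_intercept = spec.link.estimated and "intercept" in spec.class_design
        self._int_col = spec.class_design.index("intercept") if "intercept" in spec.class_design else None
        n_delta = G * q - (1 if self.fix_first_intercept else 0)
        self.n_xi, self.n_beta, self.n_delta = G - 1, p, n_delta
        self.n_chol = r * (r + 1) // 2
        self.n_sigma = 0 if spec.link.estimated else 1
        self.n_eta = spec.link.n_params if spec.link.estimated else 0
        self.n_omega = (G - 1) if spec.class_variance_scaling else 0
        self.npar = (self.n_xi + self.n_beta + self.n_delta + self.n_chol
                     + self.n_sigma + self.n_eta + self.n_omega)
        self._tril = np.tril_indices(r)

    def pack(self, pv: ParameterVector) -> np.ndarray:
        spec = self.spec
        parts = [pv.xi, pv.beta]
        delta = pv.delta.ravel()
        if self.fix_first_intercept:
            mask = np.ones(delta.size, dtype=bool)
            mask[self._int_col] = False  # first class' intercept (row 0)
            delta = delta[mask]
        parts.append(delta)
        parts.append(pv.b_chol[self._tril])
        if self.n_sigma:
            parts.append([np.log(pv.sigma_eps)])
        if self.n_eta:
            parts.append(pv.eta)
        if self.n_omega:
            om = pv.omega if pv.omega is not None else np.ones(spec.n_classes - 1)
            parts.append(np.log(om))
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def unpack(self, theta: np.ndarray) -> ParameterVector:
        spec = self.spec
        G, q, r = spec.n_classes, spec.n_class_coef, spec.n_random
        i = 0
        xi = theta[i:i + self.n_xi]; i += self.n_xi
        beta = theta[i:i + self.n_beta]; i += self.n_beta
        dflat = theta[i:i + self.n_delta]; i += self.n_delta
        if self.fix_first_intercept:
            full = np.empty(G * q)
            mask = np.ones(G * q, dtype=bool)
            mask[self._int_col] = False
            full[mask] = dflat
            full[self._int_col] = 0.0
            delta = full.reshape(G, q)
        else:
            delta = dflat.reshape(G, q)
        chol = np.zeros((r, r))
        chol[self._tril] = theta[i:i + self.n_chol]; i += self.n_chol
        sigma = 1.0
        if self.n_sigma:
            sigma = float(np.exp(theta[i])); i += 1
        eta = spec.link.eta.copy()
        if self.n_eta:
            eta = theta[i:i + self.n_eta].copy(); i += self.n_eta
        omega = None
        if self.n_omega:
            omega = np.exp(theta[i:i + self.n_omega]); i += self.n_omega
        return ParameterVector(xi, beta, delta, chol, sigma, eta, omega)


def count_free_params(spec: ModelSpec) -> int:
    return ParameterLayout(spec).npar


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


class LikelihoodEngine:
    """Precomputes design matrices and evaluates the mixture log-likelihood.

    Subjects are grouped by visit count so multivariate-normal terms are
    computed with batched Cholesky factorizations; for the spline families
    the I-spline design on the observed outcomes is built once.
    """

    def __init__(self, cohort: LongitudinalCohort, spec: ModelSpec,
                 scale_covariates: bool = False):
        self.spec = spec
        self.ids = cohort.subject_ids
        self.N = len(self.ids)
        vis = cohort.visits
        self.y_flat = vis["outcome"].to_numpy(dtype=float)

        cov_cols = sorted(set(spec.shared_design) | (set(spec.class_design) - {"intercept", "time"}))
        covdf = cohort.baseline.loc[self.ids, cov_cols].astype(float) if cov_cols else pd.DataFrame(index=self.ids)
        self.scaling: dict[str, tuple[float, float]] = {}
        if scale_covariates:
            for c in cov_cols:
                col = covdf[c]
                if col.nunique() > 2:
                    mu, sd = float(col.mean()), float(col.std(ddof=0))
                    if sd > 0:
                        covdf[c] = (col - mu) / sd
                        self.scaling[c] = (mu, sd)

        def subject_cov_row(pos, cols):
            if not cols:
                return np.empty(0)
            return covdf.iloc[pos][list(cols)].to_numpy(dtype=float)

        # group subjects by number of visits
        pos_of = {s: k for k, s in enumerate(self.ids)}
        by_n: dict[int, list] = {}
        row = 0
        for sid, grp in vis.groupby("subject_id", sort=False):
            n = len(grp)
            t = grp["time"].to_numpy(dtype=float)
            idx = np.arange(row, row + n)
            by_n.setdefault(n, []).append((pos_of[sid], t, idx))
            row += n
        # NB: groupby(sort=False) preserves first-appearance order, and visit
        # rows of one subject are contiguous in a valid cohort
        if row != len(vis):
            raise ValueError("visit rows of each subject must be contiguous")

        self.groups = []
        for n, items in sorted(by_n.items()):
            pos = np.array([it[0] for it in items])
            T = np.stack([it[1] for it in items])
            idx = np.stack([it[2] for it in items])
            m = len(items)
            Xs = np.stack([subject_cov_row(p, spec.shared_design) for p in pos]) if spec.n_shared else np.zeros((m, 0))
            U = np.empty((m, n, spec.n_class_coef))
            for j, col in enumerate(spec.class_design):
                if col == "intercept":
                    U[:, :, j] = 1.0
                elif col == "time":
                    U[:, :, j] = T
                else:
                    U[:, :, j] = np.stack([np.full(n, subject_cov_row(p, (col,))[0]) for p in pos])
            Z = np.empty((m, n, spec.n_random))
            for j, col in enumerate(spec.random_design):
                Z[:, :, j] = 1.0 if col == "intercept" else T
            self.groups.append({"n": n, "pos": pos, "T": T, "idx": idx, "X": Xs, "U": U, "Z": Z})

        if spec.link.family in SPLINE_FAMILIES:
            self._I, self._M = ispline_design(self.y_flat, spec.link.knots)
        else:
            self._I = self._M = None

    # -- link evaluation on all visits ------------------------------------

    def _transform_all(self, pv: ParameterVector) -> tuple[np.ndarray, np.ndarray]:
        link = self.spec.link
        if link.family in SPLINE_FAMILIES:
            coef = pv.eta[1:] ** 2
            h = pv.eta[0] + self._I @ coef
            hp = self._M @ coef
            return h, hp
        return link_transform(self.y_flat, link.with_eta(pv.eta))

    def loglik_parts(self, pv: ParameterVector) -> tuple[float, np.ndarray, np.ndarray]:
        """Return (total loglik, per-subject class log-densities incl. log pi, log-jacobians)."""
        spec = self.spec
        G = spec.n_classes
        log_pi = np.log(class_probabilities(pv.xi)) if G > 1 else np.zeros(1)

        h_flat, hp_flat = self._transform_all(pv)
        if np.any(hp_flat <= 0) or not np.all(np.isfinite(hp_flat)) or not np.all(np.isfinite(h_flat)):
            raise NumericalError("link transform not strictly increasing on the data")
        log_hp = np.log(hp_flat)

        B = pv.B
        sig2 = pv.sigma_eps**2
        omegas = np.ones(G)
        if pv.omega is not None:
            omegas[:-1] = pv.omega

        lw = np.empty((self.N, G))  # log pi_g + log f_ig
        jac = np.zeros(self.N)
        for grp in self.groups:
            n, pos, idx = grp["n"], grp["pos"], grp["idx"]
            H = h_flat[idx]                      # (m, n)
            jac[pos] = log_hp[idx].sum(axis=1)
            mu = np.einsum("mnq,gq->mng", grp["U"], pv.delta)
            if spec.n_shared:
                mu = mu + (grp["X"] @ pv.beta)[:, None, None]
            r = H[:, :, None] - mu               # (m, n, G)
            Z = grp["Z"]
            if pv.omega is None:
                V = np.einsum("mnr,rs,mks->mnk", Z, B, Z) + sig2 * np.eye(n)
                ll = self._mvn_logpdf(V, r)
            else:
                ll = np.empty((len(pos), G))
                for g in range(G):
                    Vg = np.einsum("mnr,rs,mks->mnk", Z, omegas[g]**2 * B, Z) + sig2 * np.eye(n)
                    ll[:, g] = self._mvn_logpdf(Vg, r[:, :, g:g + 1])[:, 0]
            lw[pos] = log_pi[None, :] + ll
        mix = logsumexp(lw, axis=1) + jac
        return float(mix.sum()), lw, jac

    @staticmethod
    def _mvn_logpdf(V: np.ndarray, r: np.ndarray) -> np.ndarray:
        """Batched centered MVN log-density: V (m,n,n), r (m,n,G) -> (m,G)."""
        n = V.shape[1]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("non-positive-definite marginal covariance") from exc
        z = np.linalg.solve(L, r)
        quad = np.einsum("mng,mng->mg", z, z)
        logdet = 2.0 * np.log(np.einsum("mii->mi", L)).sum(axis=1)
        return -0.5 * (n * _LOG_2PI + logdet[:, None] + quad)

    def total_loglik(self, pv: ParameterVector) -> float:
        return self.loglik_parts(pv)[0]

    def posterior(self, pv: ParameterVector) -> np.ndarray:
        _, lw, _ = self.loglik_parts(pv)
        lw = lw - logsumexp(lw, axis=1, keepdims=True)
        return np.exp(lw)


# ---------------------------------------------------------------------------
# public likelihood operations
# ---------------------------------------------------------------------------


def _single_subject_cohort(subject_data: pd.DataFrame, spec: ModelSpec) -> LongitudinalCohort:
    df = subject_data.copy()
    if "subject_id" not in df.columns:
        df["subject_id"] = "_s0"
    cov_cols = sorted(set(spec.shared_design) | (set(spec.class_design) - {"intercept", "time"}))
    base = df.iloc[[0]][["subject_id"] + cov_cols].set_index("subject_id") if cov_cols \
        else pd.DataFrame(index=pd.Index(df["subject_id"].iloc[:1], name="subject_id"))
    base.index.name = "subject_id"
    return LongitudinalCohort(df[["subject_id", "time", "outcome"]], base,
                              covariate_columns=tuple(cov_cols), validate=False)


def subject_loglik(subject_data: pd.DataFrame, spec: ModelSpec, params: ParameterVector) -> float:
    """Log-likelihood contribution of a single subject.

    ``log sum_g pi_g * phi(h(y_i); X_i beta + U_i delta_g, Z_i B Z_i' +
    sigma^2 I) + sum_j log h'(y_ij)`` — random effects integrated out in
    closed form.  ``subject_data`` holds columns ``time``, ``outcome`` and
    the covariates named in the model's designs.
    """
    engine = LikelihoodEngine(_single_subject_cohort(subject_data, spec), spec)
    return engine.total_loglik(params)


def total_loglik(cohort: LongitudinalCohort, spec: ModelSpec, params: ParameterVector) -> float:
    """Sum of independent subject contributions."""
    engine = LikelihoodEngine(cohort, spec)
    total, lw, jac = engine.loglik_parts(params)
    if not np.isfinite(total):
        per = logsumexp(lw, axis=1) + jac
        bad = engine.ids[~np.isfinite(per)]
        raise NumericalError(f"non-finite log-likelihood for subjects: {list(bad)[:5]}")
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitControl:
    """Optimizer controls: iteration cap and the three convergence tolerances
    (parameter change, log-likelihood change, normalized gradient criterion
    ``g' H^-1 g / npar``)."""

    max_iter: int = 500
    tol_param: float = 1e-4
    tol_loglik: float = 1e-4
    tol_grad: float = 1e-4


@dataclass
class FittedModel:
    """A maximized latent class mixed model with classification summaries."""

    spec: ModelSpec
    params: ParameterVector
    loglik: float
    npar: int
    converged: bool
    convergence: dict
    posterior: np.ndarray
    modal_class: np.ndarray
    class_counts: np.ndarray
    class_proportions: np.ndarray
    bic: float
    sabic: float
    relative_entropy: float | None
    subject_ids: np.ndarray
    covariate_scaling: dict = field(default_factory=dict)
    n_iter: int = 0
    message: str = ""

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def min_class_proportion(self) -> float:
        return float(self.class_proportions.min())

    def fixed_effects(self) -> dict:
        """Shared covariate effects and class intercepts on the original covariate scale."""
        beta = self.params.beta.copy()
        shift = 0.0
        for j, c in enumerate(self.spec.shared_design):
            if c in self.covariate_scaling:
                mu, sd = self.covariate_scaling[c]
                shift += beta[j] * mu / sd
                beta[j] = beta[j] / sd
        delta = self.params.delta.copy()
        if "intercept" in self.spec.class_design:
            delta[:, self.spec.class_design.index("intercept")] -= shift
        return {"beta": dict(zip(self.spec.shared_design, beta)),
                "delta": delta,
                "class_design": self.spec.class_design}

    def assignment_table(self) -> pd.DataFrame:
        """Per-subject modal class and posterior membership probabilities."""
        G = self.spec.n_classes
        out = pd.DataFrame({"subject_id": self.subject_ids, "modal_class": self.modal_class})
        for g in range(G):
            out[f"p_class{g + 1}"] = self.posterior[:, g]
        return out

    def to_json_dict(self) -> dict:
        pv = self.params
        return {
            "n_classes": self.spec.n_classes,
            "link_family": self.spec.link.family,
            "n_knots": self.spec.link.n_knots,
            "loglik": self.loglik,
            "npar": self.npar,
            "bic": self.bic,
            "sabic": self.sabic,
            "relative_entropy": self.relative_entropy,
            "converged": bool(self.converged),
            "convergence": {k: (float(v) if np.isscalar(v) else v) for k, v in self.convergence.items()},
            "class_proportions": self.class_proportions.tolist(),
            "estimates": {
                "xi": pv.xi.tolist(),
                "beta": dict(zip(self.spec.shared_design, pv.beta.tolist())),
                "delta": pv.delta.tolist(),
                "B": pv.B.tolist(),
                "sigma_eps": pv.sigma_eps,
                "eta": pv.eta.tolist(),
            },
            "covariate_scaling": {k: list(v) for k, v in self.covariate_scaling.items()},
        }


def bic(loglik: float, npar: int, n: int) -> float:
    """Bayesian information criterion, ``-2 l + npar * ln N`` (lower is better)."""
    return -2.0 * loglik + npar * np.log(n)


def sabic(loglik: float, npar: int, n: int) -> float:
    """Sample-size-adjusted BIC, ``-2 l + npar * ln((N + 2) / 24)``."""
    return -2.0 * loglik + npar * np.log((n + 2) / 24.0)


def relative_entropy(posterior: np.ndarray) -> float:
    """Normalized classification certainty, ``1 - sum p ln p / (N ln G)`` in [0, 1].

    1 means perfectly separated classes, 0 an uninformative classification.
    Undefined for G = 1.
    """
    post = np.asarray(posterior, dtype=float)
    if post.ndim != 2 or post.shape[1] < 2:
        raise ValueError("relative entropy requires an N x G posterior with G >= 2")
    n, g = post.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(post > 0, post * np.log(post), 0.0)
    ent = -terms.sum()
    return float(1.0 - ent / (n * np.log(g)))


def posterior_matrix(model_or_params, cohort: LongitudinalCohort,
                     spec: ModelSpec | None = None) -> np.ndarray:
    """Posterior class-membership probabilities ``p_ig`` (rows sum to 1).

    Accepts a :class:`FittedModel` or a :class:`ParameterVector` with an
    explicit ``spec``; computed in log space to avoid underflow.
    """
    if isinstance(model_or_params, FittedModel):
        spec = model_or_params.spec
        pv = model_or_params.params
        scaling = model_or_params.covariate_scaling
    else:
        pv = model_or_params
        if spec is None:
            raise ValueError("spec required when passing a ParameterVector")
        scaling = {}
    engine = LikelihoodEngine(cohort, spec)
    if scaling:
        # re-apply the scaling recorded at fit time
        engine = _scaled_engine(cohort, spec, scaling)
    return engine.posterior(pv)


def _scaled_engine(cohort, spec, scaling):
    base = cohort.baseline.copy()
    for c, (mu, sd) in scaling.items():
        base[c] = (base[c] - mu) / sd
    return LikelihoodEngine(LongitudinalCohort(cohort.visits, base, cohort.covariate_columns,
                                               validate=False), spec)


def modal_assignment(posterior: np.ndarray) -> np.ndarray:
    """Modal class per subject (1-based); ties break toward the lower class index."""
    return np.argmax(posterior, axis=1) + 1


def default_init(cohort: LongitudinalCohort, spec: ModelSpec,
                 engine: LikelihoodEngine | None = None) -> ParameterVector:
    """Data-driven starting values: pooled OLS of the default-link transform
    on time, class intercepts spread over the subject-mean distribution."""
    if engine is None:
        engine = LikelihoodEngine(cohort, spec)
    G, q, r = spec.n_classes, spec.n_class_coef, spec.n_random
    link = spec.link
    h0, _ = link_transform(cohort.outcomes(), link)
    t = cohort.visits["time"].to_numpy(dtype=float)
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, h0, rcond=None)
    resid = h0 - A @ coef
    s2 = max(float(np.var(resid)), 1e-4)

    delta = np.zeros((G, q))
    for j, col in enumerate(spec.class_design):
        if col == "intercept":
            base = 0.0 if link.estimated else coef[0]
            delta[:, j] = base + np.linspace(-0.5, 0.5, G) * np.sqrt(s2) if G > 1 else base
        elif col == "time":
            delta[:, j] = coef[1]
    if link.estimated and "intercept" in spec.class_design:
        jcol = spec.class_design.index("intercept")
        delta[:, jcol] -= delta[0, jcol]  # first class pinned at 0
    chol = np.zeros((r, r))
    diag_scale = [np.sqrt(0.5 * s2) if c == "intercept" else np.sqrt(0.05 * s2)
                  for c in spec.random_design]
    np.fill_diagonal(chol, diag_scale)
    sigma = 1.0 if link.estimated else np.sqrt(0.5 * s2)
    omega = np.ones(G - 1) if spec.class_variance_scaling else None
    return ParameterVector(np.zeros(max(G - 1, 1))[: G - 1], np.zeros(spec.n_shared),
                           delta, chol, sigma, link.eta.copy(), omega)


def fit(cohort: LongitudinalCohort, spec: ModelSpec,
        init: ParameterVector | None = None,
        control: FitControl | None = None,
        scale_covariates: bool = True) -> FittedModel:
    """Maximize the mixture likelihood by quasi-Newton (BFGS) ascent.

    Convergence requires all three criteria: ``max |d theta| < tol_param``,
    ``|d loglik| < tol_loglik`` and ``g' H^-1 g / npar < tol_grad``.  A
    non-converged fit is still returned (``converged=False``) so the
    selection layer can filter it.  Continuous covariates are z-scored
    internally for optimizer conditioning (recorded and invertible).
    """
    control = control or FitControl()
    engine = LikelihoodEngine(cohort, spec, scale_covariates=scale_covariates)
    layout = ParameterLayout(spec)
    if init is None:
        init = default_init(cohort, spec, engine)
    theta0 = layout.pack(init)

    def nll(theta):
        try:
            return -engine.total_loglik(layout.unpack(theta))
        except NumericalError:
            return 1e12

    trace: list[np.ndarray] = [theta0.copy()]
    fvals: list[float] = [nll(theta0)]

    def cb(xk):
        trace.append(np.asarray(xk, dtype=float).copy())
        fvals.append(nll(xk))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(nll, theta0, method="BFGS", callback=cb,
                       options={"maxiter": control.max_iter, "gtol": 1e-6})

    theta = res.x if res.fun <= fvals[-1] else trace[-1]
    pv = layout.unpack(theta)
    loglik = -nll(theta)

    if len(trace) >= 2:
        d_param = float(np.max(np.abs(trace[-1] - trace[-2])))
        d_ll = float(abs(fvals[-1] - fvals[-2]))
    else:
        d_param = d_ll = 0.0
    grad = res.jac
    hinv = res.hess_inv if isinstance(res.hess_inv, np.ndarray) else np.eye(len(theta))
    g_crit = float(abs(grad @ hinv @ grad) / layout.npar)
    converged = (d_param < control.tol_param and d_ll < control.tol_loglik
                 and g_crit < control.tol_grad and np.isfinite(loglik))
    convergence = {"d_param": d_param, "d_loglik": d_ll, "grad_criterion": g_crit,
                   "optimizer_status": int(res.status)}

    post = engine.posterior(pv)
    modal = modal_assignment(post)
    G = spec.n_classes
    counts = np.bincount(modal - 1, minlength=G)
    n = engine.N
    ent = relative_entropy(post) if G > 1 else None
    return FittedModel(
        spec=spec, params=pv, loglik=loglik, npar=layout.npar,
        converged=bool(converged), convergence=convergence,
        posterior=post, modal_class=modal, class_counts=counts,
        class_proportions=counts / n,
        bic=bic(loglik, layout.npar, n), sabic=sabic(loglik, layout.npar, n),
        relative_entropy=ent, subject_ids=engine.ids,
        covariate_scaling=dict(engine.scaling),
        n_iter=int(res.nit), message=str(res.message),
    )


def refit(cohort: LongitudinalCohort, fitted: FittedModel,
          control: FitControl | None = None) -> FittedModel:
    """Restart estimation from a fitted optimum (fixed-point check / polishing)."""
    return fit(cohort, fitted.spec, init=fitted.params, control=control,
               scale_covariates=bool(fitted.covariate_scaling))
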