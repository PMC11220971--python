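"""Parametric monotone link functions for the latent-process outcome model.

The observed cognitive score ``y`` is mapped to the latent-process scale by a
strictly increasing transform ``h``.  Four families are supported:

``linear``
    ``h(y) = (y - eta0) / eta1`` — two parameters (location, scale); with
    ``eta = (0, 1)`` this is the identity and the model is an ordinary
    mixture of linear mixed models.
``splines_equidistant`` / ``splines_quantile``
    ``h(y) = eta0 + sum_k w_k^2 I_k(y)`` — an intercept plus a nonnegative
    combination of quadratic I-splines (integrated M-splines) on ``n_knots``
    total knots (boundary knots at the observed outcome range, interior
    knots placed equidistantly or at empirical quantiles).  Squaring the
    coefficients enforces monotonicity; a spline link on K total knots has
    ``K + 2`` parameters (intercept + K+1 basis coefficients).
``beta``
    the outcome is min-max rescaled into (eps, 1-eps) and pushed through a
    Beta CDF with two positive shape parameters, then affinely relocated:
    4 parameters ``(log a, log b, location, log scale)``.

The Jacobian ``h'(y)`` enters the model likelihood, so every transform also
returns its derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import beta as beta_dist

FAMILIES = ("linear", "splines_equidistant", "splines_quantile", "beta")
SPLINE_FAMILIES = ("splines_equidistant", "splines_quantile")

#: Margin used to keep beta-link arguments strictly inside (0, 1).
BETA_EPS = 1e-4


class LinkRangeError(ValueError):
    """Outcome value outside the link's support (callers clamp or reject at read time)."""


@dataclass
class LinkSpec:
    """A monotone link family with its knots and current parameter vector."""

    family: str
    n_knots: int = 0
    knots: np.ndarray = field(default_factory=lambda: np.empty(0))
    eta: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown link family {self.family!r}; expected one of {FAMILIES}")
        self.knots = np.asarray(self.knots, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)

    @property
    def n_params(self) -> int:
        """Number of link parameters (free or not)."""
        if self.family == "linear":
            return 2
        if self.family == "beta":
            return 4
        return self.n_knots + 2

    @property
    def estimated(self) -> bool:
        """Whether the link parameters are estimated (linear links are fixed at identity)."""
        return self.family != "linear"

    def with_eta(self, eta) -> "LinkSpec":
        return LinkSpec(self.family, self.n_knots, self.knots.copy(), np.asarray(eta, dtype=float))


def _mspline_bases(knots: np.ndarray) -> list[tuple[BSpline, BSpline, float]]:
    """Quadratic M-spline bases, their antiderivatives (I-splines), support ends."""
    a, b = knots[0], knots[-1]
    interior = knots[1:-1]
    t = np.concatenate([[a, a, a], interior, [b, b, b]])
    order = 3  # quadratic
    n_basis = len(t) - order
    triples = []
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        # M-spline normalization: integrates to 1 over its support
        coef[j] = order / (t[j + order] - t[j])
        m = BSpline(t, coef, order - 1, extrapolate=False)
        triples.append((m, m.antiderivative(), float(t[j + order])))
    return triples


def ispline_design(y: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design matrices of the quadratic I-spline basis and its derivative.

    Returns ``(I, M)`` with shapes ``(len(y), K+1)`` for K total knots;
    each I-spline rises from 0 at the lower boundary knot to 1 at the upper.
    """
    y = np.asarray(y, dtype=float)
    a, b = knots[0], knots[-1]
    tol = 1e-9 * max(1.0, abs(b - a))
    if np.any(y < a - tol) or np.any(y > b + tol):
        raise LinkRangeError(
            f"outcome values outside link support [{a}, {b}]"
        )
    yc = np.clip(y, a, b)
    triples = _mspline_bases(knots)
    M = np.column_stack([np.nan_to_num(m(yc), nan=0.0) for m, _, _ in triples])
    I = np.column_stack([np.nan_to_num(ii(yc), nan=0.0) for _, ii, _ in triples])
    # exact value where a basis' mass is complete (guards endpoint evaluation)
    for j, (_, _, sup_hi) in enumerate(triples):
        I[yc >= sup_hi, j] = 1.0
    return I, M


def build_link(family: str, n_knots: int = 0, outcomes=None) -> LinkSpec:
    """Construct a :class:`LinkSpec` for the observed outcome distribution.

    Knots are placed over ``[min(outcomes), max(outcomes)]`` — equidistantly
    for ``splines_equidistant``, at empirical quantiles for
    ``splines_quantile``.  Default parameters approximately z-score the
    outcome, which is the estimation starting point.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown link family {family!r}")
    if family == "linear":
        return LinkSpec("linear", 0, np.empty(0), np.array([0.0, 1.0]))

    y = np.asarray(outcomes, dtype=float)
    y = y[np.isfinite(y)]
    lo, hi = float(np.min(y)), float(np.max(y))
    if not hi > lo:
        raise ValueError("degenerate outcome range: max(outcomes) must exceed min(outcomes)")
    mu, sd = float(np.mean(y)), float(np.std(y))
    sd = sd if sd > 0 else 1.0

    if family == "beta":
        # shapes a=b=1 make the CDF affine; location/scale chosen to z-score
        scale = (hi - lo) / sd
        loc = (lo - mu) / sd
        return LinkSpec("beta", 0, np.array([lo, hi]), np.array([0.0, 0.0, loc, np.log(scale)]))

    if n_knots < 2:
        raise ValueError("spline links need n_knots >= 2 (boundary knots included)")
    if n_knots > np.unique(y).size:
        raise ValueError("n_knots exceeds the number of distinct outcome values")
    if family == "splines_equidistant":
        knots = np.linspace(lo, hi, n_knots)
    else:
        probs = np.linspace(0.0, 1.0, n_knots)
        knots = np.quantile(y, probs)
        knots[0], knots[-1] = lo, hi
        if np.any(np.diff(knots) <= 0):
            # collapse duplicated quantiles toward an equidistant fallback
            knots = np.unique(knots)
            if len(knots) < n_knots:
                knots = np.linspace(lo, hi, n_knots)
    n_basis = n_knots + 1
    w = np.full(n_basis, np.sqrt((hi - lo) / sd / n_basis))
    eta0 = (lo - mu) / sd
    return LinkSpec(family, n_knots, knots, np.concatenate([[eta0], w]))


def link_transform(y, spec: LinkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate ``(h(y), h'(y))`` under the link specification.

    Raises :class:`LinkRangeError` for spline/beta links when ``y`` falls
    outside the boundary-knot support.
    """
    y = np.asarray(y, dtype=float)
    if spec.family == "linear":
        loc, scale = spec.eta
        if scale <= 0:
            raise ValueError("linear link scale must be positive")
        return (y - loc) / scale, np.full_like(y, 1.0 / scale)

    if spec.family == "beta":
        lo, hi = spec.knots
        tol = 1e-9 * max(1.0, hi - lo)
        if np.any(y < lo - tol) or np.any(y > hi + tol):
            raise LinkRangeError(f"outcome values outside link support [{lo}, {hi}]")
        log_a, log_b, loc, log_scale = spec.eta
        a, b = np.exp(log_a), np.exp(log_b)
        scale = np.exp(log_scale)
        u = BETA_EPS + (1 - 2 * BETA_EPS) * (np.clip(y, lo, hi) - lo) / (hi - lo)
        h = loc + scale * beta_dist.cdf(u, a, b)
        hp = scale * beta_dist.pdf(u, a, b) * (1 - 2 * BETA_EPS) / (hi - lo)
        return h, hp

    I, M = ispline_design(y, spec.knots)
    eta0, w = spec.eta[0], spec.eta[1:]
    coef = w**2
    return eta0 + I @ coef, M @ coef
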