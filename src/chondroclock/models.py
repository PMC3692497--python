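"""Amino-acid substitution models: JTT(+I)+Gamma with discrete rate classes.

The rate generator Q is assembled from symmetric exchangeabilities S and
equilibrium frequencies pi as Q_ij = S_ij * pi_j (i != j), rows summing to
zero, normalized so the expected rate at equilibrium is one substitution
per site.  Among-site rate heterogeneity uses k equal-probability discrete
gamma categories represented by their category means (the CODEML/PHYML
convention); an optional invariant-site class takes probability p_inv with
the remaining categories rescaled so the overall mean rate stays one.

Transition probabilities are computed from a single symmetric
eigendecomposition of Pi^{1/2} Q Pi^{-1/2}, fixed once per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincinv, gammainc

from .jtt_data import JTT_FREQUENCIES, JTT_LOWER_TRIANGLE, JTT_ORDER

N_STATES = 20


def discretize_gamma(alpha: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rates and weights of ``k`` equal-probability Gamma(alpha, alpha) classes.

    Returns ``(rates, weights)``; each class is represented by its
    conditional mean, so the weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.array([1.0]), np.array([1.0])
    # category boundaries = quantiles of Gamma(alpha, rate=alpha)
    probs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, probs)  # in units of rate 1; scale-free below
    # E[X | bin] for X~Gamma(a, a): k * (F_{a+1}(b_hi) - F_{a+1}(b_lo)),
    # with F evaluated at the same (rate-alpha) boundaries.
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    upper = gammainc(alpha + 1.0, np.where(np.isinf(edges[1:]), 1e308, edges[1:]))
    upper[np.isinf(edges[1:])] = 1.0
    lower = gammainc(alpha + 1.0, edges[:-1])
    rates = k * (upper - lower)
    rates = rates / (rates.mean())  # exact mean-1 against roundoff
    weights = np.full(k, 1.0 / k)
    return rates, weights


def _assemble_generator(
    exchangeabilities: np.ndarray, frequencies: np.ndarray
) -> np.ndarray:
    Q = exchangeabilities * frequencies[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # normalize: expected rate -sum_i pi_i Q_ii = 1
    mu = -(frequencies * np.diag(Q)).sum()
    return Q / mu


@dataclass
class SubstitutionModel:
    """A reversible amino-acid model with discrete-gamma rate classes."""

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    p_inv: float = 0.0
    name: str = "custom"

    Q: np.ndarray = field(init=False, repr=False)
    category_rates: np.ndarray = field(init=False, repr=False)
    category_weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-8 or (pi <= 0).any():
            raise ValueError("frequencies must be 20 positive values summing to 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        self.frequencies = pi / pi.sum()
        self.Q = _assemble_generator(S, self.frequencies)
        rates, weights = discretize_gamma(self.alpha, self.n_categories)
        # invariant class: probability p_inv at rate 0; variable classes are
        # rescaled by 1/(1 - p_inv) so the marginal mean rate remains 1.
        if self.p_inv > 0.0:
            rates = rates / (1.0 - self.p_inv)
        self.category_rates = rates
        self.category_weights = weights
        # symmetric eigendecomposition: B = Pi^{1/2} Q Pi^{-1/2}
        sqrt_pi = np.sqrt(self.frequencies)
        B = sqrt_pi[:, None] * self.Q / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._right = sqrt_pi[:, None] * eigvec
        # decomposition P(t) = V1 exp(Lambda t) V2 with V1 = Pi^{-1/2} U,
        # V2 = U^T Pi^{1/2}; exposed for likelihood hot loops.
        self.eigenvalues = eigval
        self.V1 = eigvec / sqrt_pi[:, None]
        self.V2 = eigvec.T * sqrt_pi[None, :]

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(
            self.exchangeabilities,
            self.frequencies,
            alpha=alpha,
            n_categories=self.n_categories,
            p_inv=self.p_inv,
            name=self.name,
        )

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows index the ancestral state."""
        if t < 0:
            raise ValueError("negative branch length")
        # P = Pi^{-1/2} U exp(L t) U^T Pi^{1/2}
        expl = np.exp(self._eigval * t)
        U = self._right / np.sqrt(self.frequencies)[:, None]  # = eigvec
        sqrt_pi = np.sqrt(self.frequencies)
        P = (U * expl[None, :]) @ (U.T * sqrt_pi[None, :])
        P = P / sqrt_pi[:, None]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r_c) over the variable-rate categories."""
        return np.stack([self.transition_matrix(t * r) for r in self.category_rates])


def jtt_matrix() -> tuple[np.ndarray, np.ndarray]:
    """The JTT exchangeability matrix and frequencies in ARNDCQEGHILKMFPSTWYV order."""
    S = np.zeros((N_STATES, N_STATES))
    idx = 0
    for j in range(N_STATES):  # column-major lower triangle
        for i in range(j + 1, N_STATES):
            S[i, j] = S[j, i] = JTT_LOWER_TRIANGLE[idx]
            idx += 1
    pi = np.array(JTT_FREQUENCIES)
    return S, pi / pi.sum()


def build_jtt(
    alpha: float = 1.0,
    n_categories: int = 4,
    p_inv: float = 0.0,
    frequencies: np.ndarray | None = None,
) -> SubstitutionModel:
    """JTT(+I)+Gamma model; pass ``frequencies`` for a +F variant."""
    S, pi = jtt_matrix()
    if frequencies is not None:
        pi = np.asarray(frequencies, dtype=float)
    return SubstitutionModel(
        S, pi, alpha=alpha, n_categories=n_categories, p_inv=p_inv, name="JTT"
    )


AA_INDEX = {aa: i for i, aa in enumerate(JTT_ORDER)}
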