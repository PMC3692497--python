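"""Amino-acid likelihood engine.

Per-site log-likelihoods are computed by Felsenstein's pruning recursion
over compressed site patterns, with gap/``X`` treated as fully ambiguous
(conditional likelihood 1 for every state).  Branch lengths are optimized
coordinate-wise with Brent's method on each branch, reusing the
conditional-likelihood vectors above and below the branch, cycling until
the log-likelihood gain drops below tolerance.  The same machinery drives
the gamma-shape estimate, two-sequence ML distances, and the site
log-likelihood vectors consumed by the topology test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .models import AA_INDEX, N_STATES, SubstitutionModel
from .seqio import Alignment
from .trees import Node, PhyloTree

BRANCH_MIN = 1e-8
BRANCH_MAX = 20.0


@dataclass
class SiteLogLikelihoods:
    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _encode(alignment: Alignment) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """State codes per taxon (-1 = missing), pattern columns and weights."""
    if alignment.alphabet != "amino-acid":
        raise ValueError("likelihood engine expects an amino-acid alignment")
    taxa = alignment.taxa
    mat = np.empty((len(taxa), alignment.n_sites), dtype=np.int8)
    for i, rec in enumerate(alignment.records):
        mat[i] = [AA_INDEX.get(ch, -1) for ch in rec.residues]
    patterns, inverse, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    codes = {t: patterns.T[i] for i, t in enumerate(taxa)}
    return codes, inverse, counts.astype(float)


class TreeLikelihood:
    """Pruning likelihood for one (tree, alignment, model) triple.

    The tree is used as given (rooted anywhere); for a reversible model the
    likelihood does not depend on the root placement.  Branch lengths live
    on the tree nodes and may be updated in place between calls.
    """

    def __init__(self, tree: PhyloTree, alignment: Alignment, model: SubstitutionModel):
        tips = set(tree.tip_names())
        taxa = set(alignment.taxa)
        if tips != taxa:
            raise ValueError(
                f"tree/alignment taxon mismatch: {sorted(tips ^ taxa)}"
            )
        self.tree = tree
        self.model = model
        self.codes, self.site_to_pattern, self.weights = _encode(alignment)
        self.n_patterns = len(self.weights)
        self.n_sites = alignment.n_sites
        # pattern is "potentially invariant" if all non-missing states agree
        self._inv_state = np.full(self.n_patterns, -1, dtype=np.int16)
        self._inv_ok = np.ones(self.n_patterns, dtype=bool)
        for codes in self.codes.values():
            seen = codes >= 0
            clash = seen & (self._inv_state >= 0) & (self._inv_state != codes)
            self._inv_ok &= ~clash
            fresh = seen & (self._inv_state < 0)
            self._inv_state[fresh] = codes[fresh]

    # -- conditional likelihoods ----------------------------------------
    def _tip_partial(self, node: Node) -> np.ndarray:
        codes = self.codes[node.name]
        part = np.ones((N_STATES, self.n_patterns))
        seen = codes >= 0
        part[:, seen] = 0.0
        part[codes[seen], np.nonzero(seen)[0]] = 1.0
        return np.broadcast_to(part, (self.model.n_categories, N_STATES, self.n_patterns))

    def _down_partials(self) -> tuple[dict[Node, np.ndarray], np.ndarray]:
        """Postorder conditionals P(data below node | state), with log-scaling."""
        partials: dict[Node, np.ndarray] = {}
        log_scale = np.zeros(self.n_patterns)
        for node in self.tree.postorder():
            if node.is_tip:
                partials[node] = self._tip_partial(node)
                continue
            acc = np.ones((self.model.n_categories, N_STATES, self.n_patterns))
            for child in node.children:
                t = max(child.length if child.length is not None else 0.0, 0.0)
                P = self.model.category_transition_matrices(t)
                acc = acc * np.matmul(P, partials[child])
            top = acc.max(axis=(0, 1))
            small = top < 1e-200
            if small.any():
                scale = np.where(top > 0, np.maximum(top, 1e-300), 1.0)
                acc = acc / scale
                log_scale = log_scale + np.log(scale)
            partials[node] = acc
        return partials, log_scale

    def _pattern_loglik(self) -> np.ndarray:
        partials, log_scale = self._down_partials()
        root_part = partials[self.tree.root]
        pi = self.model.frequencies
        w = self.model.category_weights
        lik = np.einsum("c,j,cjp->p", w, pi, root_part)
        return self._finish(lik, log_scale)

    def _finish(self, variable_lik: np.ndarray, log_scale: np.ndarray) -> np.ndarray:
        """Combine variable-rate likelihood with the invariant class."""
        p_inv = self.model.p_inv
        if p_inv > 0.0:
            pi = self.model.frequencies
            inv_lik = np.zeros(self.n_patterns)
            const = self._inv_ok
            has_state = const & (self._inv_state >= 0)
            inv_lik[has_state] = pi[self._inv_state[has_state]]
            inv_lik[const & (self._inv_state < 0)] = 1.0  # all-missing column
            # invariant part is unscaled; undo scaling on it
            lik = (1.0 - p_inv) * variable_lik + p_inv * inv_lik * np.exp(-log_scale)
        else:
            lik = variable_lik
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(lik, 1e-320)) + log_scale

    def site_log_likelihoods(self) -> SiteLogLikelihoods:
        per_pattern = self._pattern_loglik()
        return SiteLogLikelihoods(per_pattern[self.site_to_pattern])

    def log_likelihood(self) -> float:
        return float((self._pattern_loglik() * self.weights).sum())

    # -- branch-length optimization --------------------------------------
    def _edge_vectors(self, node: Node, partials: dict[Node, np.ndarray]):
        """pi-weighted outside vector at the parent and inside vector at node.

        logL(t) = sum_p w_p log sum_c w_c sum_x out[c,x,p] (P_c(t) in)[x,p]
        where out already includes pi (placed at the parent, valid under
        reversibility).
        """
        parent = node.parent
        # outside conditional at `parent` excluding the subtree of `node`,
        # built root-down along the path.
        path = []
        p = parent
        while p is not None:
            path.append(p)
            p = p.parent
        path.reverse()  # root ... parent
        out = np.ones((self.model.n_categories, N_STATES, self.n_patterns))
        for anc, below in zip(path, path[1:] + [node]):
            for child in anc.children:
                if child is below:
                    continue
                t = max(child.length if child.length is not None else 0.0, 0.0)
                P = self.model.category_transition_matrices(t)
                out = out * np.einsum("cij,cjp->cip", P, partials[child])
            if below is not node:
                t = max(below.length if below.length is not None else 0.0, 0.0)
                P = self.model.category_transition_matrices(t)
                # flow downward across the edge (anc, below): reversible, so
                # out_below(y) = sum_x out_anc(x) pi_x P_xy / pi_y; fold pi in
                # at the end instead by carrying pi-weighted vectors.
                pi = self.model.frequencies
                W = out * pi[None, :, None]
                out = np.matmul(P.transpose(0, 2, 1), W) / pi[None, :, None]
        pi = self.model.frequencies
        return out * pi[None, :, None], partials[node]

    def _edge_loglik_factory(self, out_pi, inner):
        """Fast per-edge logL(t) via the eigenbasis of Q.

        sum_xy out_pi[x] P_xy(t r_c) inner[y]
          = sum_k exp(lambda_k t r_c) (out_pi V1)[k] (V2 inner)[k].
        """
        m = self.model
        A = np.matmul(m.V1.T[None, :, :], out_pi)
        B = np.matmul(m.V2[None, :, :], inner)
        AB = A * B
        lam = m.eigenvalues
        rates = m.category_rates
        w = m.category_weights

        def loglik(t: float) -> float:
            e = np.exp(np.outer(rates, lam) * max(t, 0.0))  # (c, k)
            lik = ((w[:, None] * e)[:, :, None] * AB).sum(axis=(0, 1))
            per_pattern = self._finish(lik, np.zeros(self.n_patterns))
            return float((per_pattern * self.weights).sum())

        return loglik

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_rounds: int = 20, xtol: float = 1e-7,
        warn_on_nonconvergence: bool = True,
    ) -> float:
        """Coordinate-wise ML branch lengths in place; returns final logL.

        One round visits every branch in postorder, refreshing the
        conditional of each internal node from its (already-refreshed)
        children before optimizing its branch, so every 1-D optimization
        sees current values.  Partials here are unscaled; suitable for the
        tree depths this pipeline targets.
        """
        last = self.log_likelihood()
        ncat = self.model.n_categories
        for _ in range(max_rounds):
            partials: dict[Node, np.ndarray] = {}

            def refresh(node: Node) -> None:
                acc = np.ones((ncat, N_STATES, self.n_patterns))
                for child in node.children:
                    t = max(child.length or 0.0, 0.0)
                    P = self.model.category_transition_matrices(t)
                    acc = acc * np.matmul(P, partials[child])
                partials[node] = acc

            for node in self.tree.postorder():
                if node.is_tip:
                    partials[node] = self._tip_partial(node)
                else:
                    refresh(node)

            for node in self.tree.postorder():
                if not node.is_tip:
                    refresh(node)
                if node.parent is None:
                    continue
                out_pi, inner = self._edge_vectors(node, partials)
                loglik = self._edge_loglik_factory(out_pi, inner)
                res = minimize_scalar(
                    lambda t: -loglik(t),
                    bounds=(BRANCH_MIN, BRANCH_MAX),
                    method="bounded",
                    options={"xatol": xtol},
                )
                if loglik(float(res.x)) >= loglik(node.length or 0.0):
                    node.length = float(res.x)
            current = self.log_likelihood()
            if current < last - 1e-6:
                warnings.warn("branch-length pass decreased logL; stopping")
                break
            if current - last < tol:
                last = current
                break
            last = current
        else:
            if warn_on_nonconvergence:
                warnings.warn(
                    "branch-length optimization did not converge; best-so-far"
                )
        return last


def site_log_likelihoods(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> SiteLogLikelihoods:
    for node in tree.postorder():
        if node.parent is not None and node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    return TreeLikelihood(tree, alignment, model).site_log_likelihoods()


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 20,
    warn_on_nonconvergence: bool = True,
) -> tuple[PhyloTree, float]:
    """Return a copy of ``tree`` with ML branch lengths, and its logL."""
    work = tree.copy()
    for node in work.postorder():
        if node.parent is not None and (node.length is None or node.length <= 0):
            node.length = 0.1
    engine = TreeLikelihood(work, alignment, model)
    logl = engine.optimize_branch_lengths(
        tol=tol, max_rounds=max_rounds,
        warn_on_nonconvergence=warn_on_nonconvergence,
    )
    return work, logl


def estimate_alpha(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.02, 100.0),
    optimize_branches: bool = True,
    cycles: int = 2,
) -> tuple[float, PhyloTree, float]:
    """ML estimate of the gamma shape (bounded 1-D search on log-alpha).

    Alternates alpha search with branch-length re-optimization for
    ``cycles`` rounds when ``optimize_branches`` is set.  Returns
    ``(alpha_hat, tree_with_ml_lengths, logL)``.
    """
    if alignment.n_sites < 2:
        raise ValueError("need at least 2 sites to estimate alpha")
    work = tree.copy()
    alpha = model.alpha
    logl = None
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    for _ in range(cycles if optimize_branches else 1):
        if optimize_branches:
            work, _ = optimize_branch_lengths(work, alignment, model.with_alpha(alpha))

        def neg(log_a: float) -> float:
            m = model.with_alpha(float(np.exp(log_a)))
            return -TreeLikelihood(work, alignment, m).log_likelihood()

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        alpha = float(np.exp(res.x))
        logl = -float(res.fun)
    if alpha >= bounds[1] * 0.99 or alpha <= bounds[0] * 1.01:
        warnings.warn(f"alpha estimate {alpha:.4g} hit the search bound")
    return alpha, work, logl


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites; complete deletion must be done already."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) == 0:
        raise ValueError("no columns to compare")
    diffs = sum(1 for a, b in zip(seq_a, seq_b) if a != b)
    return diffs / len(seq_a)


def pairwise_ml_distance(
    seq_a: str,
    seq_b: str,
    model: SubstitutionModel,
    max_distance: float = BRANCH_MAX,
) -> float:
    """ML distance (substitutions/site) between two aligned sequences.

    Columns with a gap/``X`` in either sequence are ignored.  A saturated
    pair (likelihood still rising at the search bound) warns and returns
    the bound.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    counts = np.zeros((N_STATES, N_STATES))
    for a, b in zip(seq_a, seq_b):
        ia, ib = AA_INDEX.get(a, -1), AA_INDEX.get(b, -1)
        if ia >= 0 and ib >= 0:
            counts[ia, ib] += 1
    if counts.sum() == 0:
        raise ValueError("no jointly determined columns")
    pi = model.frequencies
    w = model.category_weights
    same = np.eye(N_STATES, dtype=bool)

    def neg(t: float) -> float:
        Pmix = np.einsum(
            "c,cij->ij", w, model.category_transition_matrices(max(t, 0.0))
        )
        joint = (1.0 - model.p_inv) * pi[:, None] * Pmix
        if model.p_inv > 0.0:
            joint = joint + model.p_inv * np.where(same, pi[:, None], 0.0)
        return -float((counts * np.log(np.maximum(joint, 1e-320))).sum())

    res = minimize_scalar(
        neg, bounds=(0.0, max_distance), method="bounded", options={"xatol": 1e-8}
    )
    t_hat = float(res.x)
    if t_hat > 0.98 * max_distance:
        warnings.warn("saturated pair: ML distance at the upper bound")
        return max_distance
    return t_hat
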