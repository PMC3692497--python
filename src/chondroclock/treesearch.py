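"""Tree construction and search: neighbor joining and NNI hill-climbing.

NJ follows the standard Saitou-Nei agglomeration with the Studier-Keppler
Q-criterion; ties are broken on the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest tip) so the result
is invariant to input ordering.  The ML search hill-climbs over
nearest-neighbor-interchange rearrangements, re-optimizing branch lengths
for every candidate, until no neighbor improves the log-likelihood.
"""

from __future__ import annotations

import numpy as np

from .likelihood import TreeLikelihood, optimize_branch_lengths
from .models import SubstitutionModel
from .seqio import Alignment
from .trees import Node, PhyloTree


def nj_tree(distance_matrix: np.ndarray, labels: list[str]) -> PhyloTree:
    """Neighbor-joining tree (unrooted; trifurcating root for n >= 3).

    For an additive distance matrix this reconstructs the generating
    topology and branch lengths exactly.  Negative branch-length estimates
    are clamped to zero.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix / labels size mismatch")
    if not np.allclose(D, D.T) or (np.diag(D) != 0).any() or (D < 0).any():
        raise ValueError("need a symmetric, non-negative, zero-diagonal matrix")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")

    nodes = [Node(lab) for lab in labels]
    names = list(labels)  # smallest tip label per cluster
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((names[idx[a]], names[idx[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = idx[a], idx[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = Node()
        ni, nj_ = nodes[i], nodes[j]
        ni.length = max(li, 0.0)
        nj_.length = max(lj, 0.0)
        parent.add_child(ni)
        parent.add_child(nj_)
        # distances from the new node
        new = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new
        D[:, i] = new
        D[i, i] = 0.0
        nodes[i] = parent
        names[i] = min(names[i], names[j])
        active.remove(j)

    root = Node()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for ind, ln in zip((i, j, k), (li, lj, lk)):
            nodes[ind].length = max(ln, 0.0)
            root.add_child(nodes[ind])
    elif len(active) == 2:
        i, j = active
        nodes[i].length = D[i, j] / 2.0
        nodes[j].length = D[i, j] / 2.0
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    else:
        root = nodes[active[0]]
    return PhyloTree(root)


def _nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees one NNI away, around every internal edge.

    An internal edge (u, v) with v's children (c1, c2) and a sibling s of v
    yields the two alternative resolutions: swap s with c1, swap s with c2.
    """
    out = []
    nodes = list(tree.postorder())
    for vi, v in enumerate(nodes):
        if v.is_tip or v.parent is None:
            continue
        u = v.parent
        sibs = [c for c in u.children if c is not v]
        if not sibs:
            continue
        s = sibs[0]
        for ci in range(2):
            work = tree.copy()
            wnodes = list(work.postorder())
            wv = wnodes[vi]
            wu = wv.parent
            ws = [c for c in wu.children if c is not wv][0]
            wc = wv.children[ci]
            # swap ws <-> wc
            wu.children[wu.children.index(ws)] = wc
            wv.children[wv.children.index(wc)] = ws
            wc.parent = wu
            ws.parent = wv
            out.append(work)
    return out


def ml_search_nni(
    start_tree: PhyloTree,
    alignment: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-4,
    max_moves: int = 50,
) -> tuple[PhyloTree, float]:
    """Hill-climb over NNI neighborhoods from ``start_tree``.

    Candidate neighbors are scored with a coarse branch-length pass (warm
    started from the current lengths); the accepted move is then refined
    to full tolerance.  Returns the tree (with ML branch lengths) none of
    whose NNI neighbors improves the log-likelihood, and its logL.
    """
    current, current_logl = optimize_branch_lengths(start_tree, alignment, model)
    for _ in range(max_moves):
        best, best_logl = None, current_logl
        for cand in _nni_neighbors(current):
            cand_opt, logl = optimize_branch_lengths(
                cand, alignment, model, tol=1e-2, max_rounds=3,
                warn_on_nonconvergence=False,
            )
            if logl > best_logl + tol:
                best, best_logl = cand_opt, logl
        if best is None:
            break
        current, current_logl = optimize_branch_lengths(best, alignment, model)
    return current, current_logl


def ml_distance_matrix(
    alignment: Alignment, model: SubstitutionModel
) -> tuple[np.ndarray, list[str]]:
    """Pairwise ML distances for every taxon pair (for NJ starting trees)."""
    from .likelihood import pairwise_ml_distance

    taxa = alignment.taxa
    n = len(taxa)
    D = np.zeros((n, n))
    seqs = {r.identifier: r.residues for r in alignment.records}
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_ml_distance(seqs[taxa[i]], seqs[taxa[j]], model)
    return D, taxa
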