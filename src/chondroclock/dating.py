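"""Bayesian relaxed-clock node dating with fossil calibrations.

The model follows the independent-rates relaxed clock: a fixed rooted
topology, node ages t (internal time unit: 100 My; Ma at the interfaces),
and one substitution rate per branch with log r ~ Normal(log mu, sigma2)
(mu is therefore the median rate).  Gamma priors are placed on the mean
rate mu (default G(1, 5.2) per 100 My) and on the log-rate drift variance
sigma2 (default G(1, 5.6)).  Fossil constraints enter as soft
minimum+maximum bounds (95% plateau between the bounds, a power tail
below carrying 2.5% and a shifted-exponential tail above carrying 2.5%,
density continuous at both bounds), as soft maximum-only bounds, or as
hard lower bounds.  Uncalibrated node ages are uniform conditional on the
root age subject to the parent-older-than-child ordering.

Sampling is Metropolis-within-Gibbs with sliding-window proposals
(log-scale for positive rate parameters), windows auto-tuned to a
20-40% acceptance rate during burn-in and frozen afterwards.  The
sequence likelihood is either the exact pruning likelihood or, by
default, a normal approximation around the ML branch lengths of the
unrooted topology (one term per branch, curvature from the observed
Fisher information; the two root-child branches are merged into the
single identifiable root-spanning branch).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .likelihood import BRANCH_MIN, TreeLikelihood, optimize_branch_lengths
from .models import SubstitutionModel
from .seqio import Alignment, Calibration
from .trees import Node, PhyloTree

TIME_UNIT_MA = 100.0


# ---------------------------------------------------------------------------
# calibration densities (arguments in Ma)
# ---------------------------------------------------------------------------

def soft_bound_log_prior(
    t: float, lower: float, upper: float, tail_prob: float = 0.025
) -> float:
    """Log-density of the soft min/max calibration at age ``t`` (Ma).

    Uniform plateau on (lower, upper) carrying 1 - 2*tail_prob; a power
    tail on (0, lower) and a shifted-exponential tail above upper, each
    carrying tail_prob, both continuous at the bounds.  Integrates to 1.
    """
    if not lower < upper:
        raise ValueError("need lower < upper")
    if t <= 0:
        return -math.inf
    p = tail_prob
    h = (1.0 - 2.0 * p) / (upper - lower)
    if t < lower:
        theta = h * lower / p
        return math.log(p * theta / lower) + (theta - 1.0) * math.log(t / lower)
    if t > upper:
        lam = h / p
        return math.log(p * lam) - lam * (t - upper)
    return math.log(h)


def soft_bound_cdf(t: float, lower: float, upper: float, tail_prob: float = 0.025) -> float:
    p = tail_prob
    h = (1.0 - 2.0 * p) / (upper - lower)
    if t <= 0:
        return 0.0
    if t < lower:
        theta = h * lower / p
        return p * (t / lower) ** theta
    if t <= upper:
        return p + h * (t - lower)
    lam = h / p
    return 1.0 - p * math.exp(-lam * (t - upper))


def soft_upper_log_prior(t: float, upper: float, tail_prob: float = 0.025) -> float:
    """Maximum-only soft bound: uniform on (0, upper), exponential tail above."""
    if t <= 0:
        return -math.inf
    p = tail_prob
    h = (1.0 - p) / upper
    if t <= upper:
        return math.log(h)
    lam = h / p
    return math.log(p * lam) - lam * (t - upper)


def hard_lower_log_prior(t: float, lower: float) -> float:
    """Hard minimum: -inf below ``lower``, flat above (bounded by the node
    ordering and the root age prior in which it is embedded)."""
    if lower <= 0:
        raise ValueError("lower bound must be positive")
    return 0.0 if t >= lower else -math.inf


def calibration_log_density(cal: Calibration, t_ma: float, tail_prob: float = 0.025) -> float:
    if cal.style == "soft":
        return soft_bound_log_prior(t_ma, cal.lower_Ma, cal.upper_Ma, tail_prob)
    if cal.style == "soft-upper":
        return soft_upper_log_prior(t_ma, cal.upper_Ma, tail_prob)
    return hard_lower_log_prior(t_ma, cal.lower_Ma)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockPriors:
    """Gamma priors (shape, rate) on the clock hyperparameters."""

    rgene_shape: float = 1.0
    rgene_rate: float = 5.2
    sigma2_shape: float = 1.0
    sigma2_rate: float = 5.6

    def __post_init__(self) -> None:
        for v in (self.rgene_shape, self.rgene_rate, self.sigma2_shape, self.sigma2_rate):
            if v <= 0:
                raise ValueError("prior shapes and rates must be positive")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC schedule; defaults follow the full production schedule."""

    burn_in: int = 50000
    sample_every: int = 20
    n_samples: int = 200000
    seed: int = 0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if min(self.burn_in, self.sample_every, self.n_samples, self.n_replicates) < 1:
            raise ValueError("chain settings must be positive")


#: desk-scale schedule used throughout the test-suite simulations
TEST_CHAIN = ChainSettings(burn_in=5000, sample_every=2, n_samples=20000)


@dataclass
class DatingModel:
    topology: PhyloTree
    calibrations: list[Calibration]
    model: SubstitutionModel | None = None
    mode: str = "approximate"  # or "exact"
    tail_prob: float = 0.025

    def __post_init__(self) -> None:
        if self.mode not in ("approximate", "exact"):
            raise ValueError("mode must be 'approximate' or 'exact'")
        if not self.topology.is_rooted:
            raise ValueError("dating requires a rooted (bifurcating-root) topology")


@dataclass
class Trace:
    """Posterior samples; ages in 100-My time units, rates per time unit."""

    samples: pd.DataFrame
    node_labels: list[str]
    branch_labels: list[str]
    seed: int


# ---------------------------------------------------------------------------
# approximate likelihood scaffolding
# ---------------------------------------------------------------------------

def _unroot(tree: PhyloTree) -> tuple[PhyloTree, str, str]:
    """Copy of ``tree`` with the root suppressed (trifurcating root).

    Returns the unrooted tree and the labels of the two former root
    children whose branches were merged.
    """
    work = tree.copy()
    left, right = work.root.children
    keep, fold = (left, right) if not left.is_tip else (right, left)
    if keep.is_tip:
        raise ValueError("cannot unroot a 2-tip tree")
    l_len = (left.length or 0.1) + (right.length or 0.1)
    fold.length = l_len
    fold.parent = keep
    keep.children.append(fold)
    keep.length = None
    keep.parent = None
    return PhyloTree(keep), _node_key(left), _node_key(right)


def _node_key(node: Node) -> str:
    return node.name if node.name else "|".join(sorted(node.tip_set()))


def fit_branch_length_approximation(
    tree: PhyloTree, alignment: Alignment, model: SubstitutionModel
) -> dict[str, tuple[float, float]]:
    """ML branch lengths and normal-approximation SDs on the unrooted tree.

    Keys are the child-node labels of the rooted topology; the two root
    children share the single merged entry under the key ``"__root__"``.
    The SD of each branch comes from the observed Fisher information
    (finite-difference curvature of the per-branch log-likelihood at the
    ML length).
    """
    unrooted, left_key, right_key = _unroot(tree)
    fitted, _ = optimize_branch_lengths(unrooted, alignment, model)
    engine = TreeLikelihood(fitted, alignment, model)
    partials, _ = engine._down_partials()
    out: dict[str, tuple[float, float]] = {}
    for node in fitted.postorder():
        if node.parent is None:
            continue
        out_pi, inner = engine._edge_vectors(node, partials)
        f = engine._edge_loglik_factory(out_pi, inner)
        b = max(node.length, BRANCH_MIN)
        h = max(1e-4, 0.05 * b)
        lo = max(b - h, BRANCH_MIN)
        d2 = (f(b + h) - 2.0 * f(b) + f(lo)) / ((b + h - lo) / 2.0) ** 2
        if d2 >= -1e-9:
            warnings.warn(f"flat curvature on branch {_node_key(node)}; widening")
            sd = 1.0
        else:
            sd = 1.0 / math.sqrt(-d2)
        key = _node_key(node)
        out[key] = (b, sd)
    merged_key = left_key if left_key in out else right_key
    out["__root__"] = out.pop(merged_key)
    return out


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Tuned:
    __slots__ = ("width", "tries", "accepts")

    def __init__(self, width: float):
        self.width = width
        self.tries = 0
        self.accepts = 0

    def record(self, accepted: bool, tuning: bool) -> None:
        self.tries += 1
        self.accepts += accepted
        if tuning and self.tries >= 100:
            rate = self.accepts / self.tries
            if rate > 0.4:
                self.width *= 1.4
            elif rate < 0.2:
                self.width /= 1.4
            self.tries = self.accepts = 0


def run_mcmc(
    alignment: Alignment | None,
    dating_model: DatingModel,
    priors: ClockPriors = ClockPriors(),
    settings: ChainSettings = ChainSettings(),
    prior_only: bool = False,
    branch_approx: dict[str, tuple[float, float]] | None = None,
) -> Trace:
    """Sample node ages, branch rates, mu and sigma2.

    ``prior_only`` switches the sequence likelihood off (the standard
    sampler validation against the calibration densities).  For repeated
    runs on the same data, pass a precomputed ``branch_approx`` from
    :func:`fit_branch_length_approximation`.
    """
    tree = dating_model.topology.copy()
    rng = np.random.default_rng(settings.seed)

    internals = [n for n in tree.postorder() if not n.is_tip]
    index = {id(n): i for i, n in enumerate(internals)}
    labels = []
    for i, n in enumerate(internals):
        labels.append(n.name if n.name else f"node{i}")
    root_idx = index[id(tree.root)]

    # children of each internal node: (is_tip, internal index)
    child_internal: list[list[int]] = [[] for _ in internals]
    parent_of: list[int] = [-1] * len(internals)
    for n in internals:
        for c in n.children:
            if not c.is_tip:
                child_internal[index[id(n)]].append(index[id(c)])
                parent_of[index[id(c)]] = index[id(n)]

    # calibrations -> internal index
    cal_of: dict[int, Calibration] = {}
    for cal in dating_model.calibrations:
        node = tree.find_clade(cal.clade_tips)  # raises if clade absent
        if node.is_tip:
            raise ValueError("calibration on a single tip is not meaningful")
        i = index[id(node)]
        if i in cal_of:
            raise ValueError(f"node {labels[i]} carries two calibrations")
        cal_of[i] = cal

    root_cal = cal_of.get(root_idx)
    if root_cal is None or root_cal.upper_Ma is None:
        uppers = [c.upper_Ma for c in cal_of.values() if c.upper_Ma is not None]
        if not uppers:
            raise ValueError("no upper bound anywhere: the root age prior is improper")
        root_upper = max(uppers) * 1.5 / TIME_UNIT_MA
        warnings.warn(
            f"root has no calibration with an upper bound; using uniform(0, "
            f"{root_upper * TIME_UNIT_MA:.1f} Ma) from the oldest calibration maximum"
        )
    else:
        root_upper = None  # density supplies the bound

    n_uncal_nonroot = sum(
        1 for i in range(len(internals)) if i != root_idx and i not in cal_of
    )

    # branches: one rate per non-root node (tips included)
    branch_nodes = [n for n in tree.postorder() if n.parent is not None]
    branch_ids = {id(n): k for k, n in enumerate(branch_nodes)}
    branch_labels = [_node_key(n) for n in branch_nodes]
    # branch -> (child internal idx or -1 for tips, parent internal idx)
    branch_child: list[int] = []
    branch_parent: list[int] = []
    for n in branch_nodes:
        branch_child.append(index[id(n)] if not n.is_tip else -1)
        branch_parent.append(index[id(n.parent)])
    root_child_branches = [branch_ids[id(c)] for c in tree.root.children]

    # likelihood scaffolding
    mode = dating_model.mode
    exact_engine = None
    if prior_only:
        mode = "prior"
    elif mode == "approximate":
        if branch_approx is None:
            if alignment is None or dating_model.model is None:
                raise ValueError("approximate mode needs an alignment and model")
            branch_approx = fit_branch_length_approximation(
                tree, alignment, dating_model.model
            )
        bhat = [0.0] * len(branch_nodes)
        bsd = [1.0] * len(branch_nodes)
        for k, n in enumerate(branch_nodes):
            if k in root_child_branches:
                continue
            b, sd = branch_approx[_node_key(n)]
            bhat[k], bsd[k] = b, sd
        root_bhat, root_bsd = branch_approx["__root__"]
    else:
        if alignment is None or dating_model.model is None:
            raise ValueError("exact mode needs an alignment and model")
        exact_engine = TreeLikelihood(tree, alignment, dating_model.model)

    # ---- state initialization ------------------------------------------
    max_lower_below = [0.0] * len(internals)
    for i, n in enumerate(internals):  # postorder: children first
        lo = 0.0
        cal = cal_of.get(i)
        if cal is not None and cal.lower_Ma is not None:
            lo = cal.lower_Ma / TIME_UNIT_MA
        for j in child_internal[i]:
            lo = max(lo, max_lower_below[j])
        max_lower_below[i] = lo

    ages = [0.0] * len(internals)
    if root_cal is not None and root_cal.style == "soft":
        ages[root_idx] = 0.5 * (root_cal.lower_Ma + root_cal.upper_Ma) / TIME_UNIT_MA
    elif root_cal is not None and root_cal.upper_Ma is not None:
        ages[root_idx] = 0.75 * root_cal.upper_Ma / TIME_UNIT_MA
    else:
        ages[root_idx] = 0.75 * root_upper
    ages[root_idx] = max(ages[root_idx], max_lower_below[root_idx] * 1.05 + 0.01)
    # internals are postorder, so reversed order visits parents before children
    for i in reversed(range(len(internals))):
        if i == root_idx:
            continue
        p = parent_of[i]
        lo = max_lower_below[i]
        ages[i] = lo + 0.75 * (ages[p] - lo) if ages[p] > lo else ages[p] * 0.9
    for i in range(len(internals)):
        p = parent_of[i]
        if p >= 0 and not ages[p] > ages[i] > 0:
            raise ValueError("could not find ages satisfying the calibrations")

    mu = priors.rgene_shape / priors.rgene_rate
    sigma2 = priors.sigma2_shape / priors.sigma2_rate
    log_rates = [math.log(mu)] * len(branch_nodes)

    # ---- densities ------------------------------------------------------
    tail = dating_model.tail_prob

    def age_prior_term(i: int, t: float) -> float:
        cal = cal_of.get(i)
        if cal is not None:
            v = calibration_log_density(cal, t * TIME_UNIT_MA, tail)
        elif i == root_idx:
            v = 0.0 if 0.0 < t < root_upper else -math.inf
        else:
            v = 0.0
        return v

    def rate_prior_term(y: float, mu_: float, s2: float) -> float:
        # y = log r; N(log mu, s2) density in y
        return -0.5 * math.log(2.0 * math.pi * s2) - (y - math.log(mu_)) ** 2 / (2.0 * s2)

    def gamma_logpdf(x: float, shape: float, rate: float) -> float:
        if x <= 0:
            return -math.inf
        return shape * math.log(rate) - math.lgamma(shape) + (shape - 1.0) * math.log(x) - rate * x

    def child_age(i_or_tip: int) -> float:
        return ages[i_or_tip] if i_or_tip >= 0 else 0.0

    def branch_length(k: int) -> float:
        return math.exp(log_rates[k]) * (
            ages[branch_parent[k]] - child_age(branch_child[k])
        )

    def branch_loglik(k: int) -> float:
        if mode == "prior":
            return 0.0
        if mode == "approximate":
            if k in root_child_branches:
                b = sum(branch_length(kk) for kk in root_child_branches)
                return -0.5 * ((b - root_bhat) / root_bsd) ** 2
            return -0.5 * ((branch_length(k) - bhat[k]) / bsd[k]) ** 2
        return 0.0  # exact mode recomputes globally

    def exact_loglik() -> float:
        for n, k in ((n, branch_ids[id(n)]) for n in branch_nodes):
            n.length = max(branch_length(k), BRANCH_MIN)
        return exact_engine.log_likelihood()

    def touching_branches(i: int) -> list[int]:
        ks = []
        for k in range(len(branch_nodes)):
            if branch_parent[k] == i or branch_child[k] == i:
                ks.append(k)
        return ks

    branches_of_node = [touching_branches(i) for i in range(len(internals))]

    def local_loglik(ks: list[int]) -> float:
        if mode == "exact":
            return exact_loglik()
        seen_root = False
        tot = 0.0
        for k in ks:
            if mode == "approximate" and k in root_child_branches:
                if seen_root:
                    continue
                seen_root = True
            tot += branch_loglik(k)
        return tot

    # ---- proposal widths -------------------------------------------------
    age_win = [_Tuned(max(0.05, 0.1 * ages[root_idx])) for _ in internals]
    rate_win = [_Tuned(0.5) for _ in branch_nodes]
    mu_win = _Tuned(0.5)
    s2_win = _Tuned(0.5)

    n_iter = settings.burn_in + settings.n_samples * settings.sample_every
    kept_ages = np.empty((settings.n_samples, len(internals)))
    kept_rates = np.empty((settings.n_samples, len(branch_nodes)))
    kept_hyper = np.empty((settings.n_samples, 2))
    kept = 0

    uniform = rng.random
    for it in range(n_iter):
        tuning = it < settings.burn_in
        # -- node ages
        for i in range(len(internals)):
            lo = max((ages[j] for j in child_internal[i]), default=0.0)
            hi = ages[parent_of[i]] if i != root_idx else math.inf
            w = age_win[i]
            t_old = ages[i]
            t_new = t_old + (uniform() * 2.0 - 1.0) * w.width
            ok = lo < t_new < hi
            if ok:
                old_term = age_prior_term(i, t_old) + local_loglik(branches_of_node[i])
                if i == root_idx and n_uncal_nonroot:
                    old_term -= n_uncal_nonroot * math.log(t_old)
                ages[i] = t_new
                new_term = age_prior_term(i, t_new) + local_loglik(branches_of_node[i])
                if i == root_idx and n_uncal_nonroot:
                    new_term -= n_uncal_nonroot * math.log(t_new)
                if new_term - old_term >= 0 or uniform() < math.exp(new_term - old_term):
                    w.record(True, tuning)
                else:
                    ages[i] = t_old
                    w.record(False, tuning)
            else:
                w.record(False, tuning)
        # -- branch rates
        for k in range(len(branch_nodes)):
            w = rate_win[k]
            y_old = log_rates[k]
            y_new = y_old + (uniform() * 2.0 - 1.0) * w.width
            old_term = rate_prior_term(y_old, mu, sigma2) + local_loglik([k])
            log_rates[k] = y_new
            new_term = rate_prior_term(y_new, mu, sigma2) + local_loglik([k])
            if new_term - old_term >= 0 or uniform() < math.exp(new_term - old_term):
                w.record(True, tuning)
            else:
                log_rates[k] = y_old
                w.record(False, tuning)
        # -- mu (log-slide; Jacobian folds into the gamma density over log mu)
        for w, which in ((mu_win, "mu"), (s2_win, "s2")):
            x_old = mu if which == "mu" else sigma2
            y_old = math.log(x_old)
            y_new = y_old + (uniform() * 2.0 - 1.0) * w.width
            x_new = math.exp(y_new)
            if which == "mu":
                old_term = gamma_logpdf(x_old, priors.rgene_shape, priors.rgene_rate) + y_old
                new_term = gamma_logpdf(x_new, priors.rgene_shape, priors.rgene_rate) + y_new
                for y in log_rates:
                    old_term += rate_prior_term(y, x_old, sigma2)
                    new_term += rate_prior_term(y, x_new, sigma2)
            else:
                old_term = gamma_logpdf(x_old, priors.sigma2_shape, priors.sigma2_rate) + y_old
                new_term = gamma_logpdf(x_new, priors.sigma2_shape, priors.sigma2_rate) + y_new
                for y in log_rates:
                    old_term += rate_prior_term(y, mu, x_old)
                    new_term += rate_prior_term(y, mu, x_new)
            if new_term - old_term >= 0 or uniform() < math.exp(new_term - old_term):
                if which == "mu":
                    mu = x_new
                else:
                    sigma2 = x_new
                w.record(True, tuning)
            else:
                w.record(False, tuning)
        # -- record
        if it >= settings.burn_in and (it - settings.burn_in) % settings.sample_every == 0:
            if kept < settings.n_samples:
                kept_ages[kept] = ages
                kept_rates[kept] = np.exp(log_rates)
                kept_hyper[kept] = (mu, sigma2)
                kept += 1

    data = {"mu": kept_hyper[:kept, 0], "sigma2": kept_hyper[:kept, 1]}
    for i, lab in enumerate(labels):
        data[f"t_{lab}"] = kept_ages[:kept, i]
    for k, lab in enumerate(branch_labels):
        data[f"r_{lab}"] = kept_rates[:kept, k]
    return Trace(pd.DataFrame(data), labels, branch_labels, settings.seed)


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    nodes: pd.DataFrame  # node, mean_Ma, median_Ma, ci_low_Ma, ci_high_Ma
    densities: dict[str, tuple[np.ndarray, np.ndarray]]
    branch_rates: pd.Series


def summarize_trace(trace: Trace, grid_points: int = 512) -> PosteriorSummary:
    """Per-node posterior mean/median/95% equal-tail CI (Ma) + densities."""
    if trace.samples.empty:
        raise ValueError("empty trace")
    rows = []
    densities = {}
    for lab in trace.node_labels:
        x = trace.samples[f"t_{lab}"].to_numpy() * TIME_UNIT_MA
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        mean = float(x.mean())
        assert lo <= med <= hi
        rows.append(
            {"node": lab, "mean_Ma": mean, "median_Ma": float(med),
             "ci_low_Ma": float(lo), "ci_high_Ma": float(hi)}
        )
        grid = np.linspace(x.min(), x.max(), grid_points)
        if x.std() > 0:
            dens = gaussian_kde(x)(grid)
        else:
            dens = np.zeros(grid_points)
        densities[lab] = (grid, dens)
    rates = pd.Series(
        {lab: float(trace.samples[f"r_{lab}"].mean()) for lab in trace.branch_labels},
        name="mean_rate_per_time_unit",
    )
    return PosteriorSummary(pd.DataFrame(rows), densities, rates)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs until the pair sum goes non-positive (Geyer)
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    passed: bool


def convergence_check(
    trace_a: Trace, trace_b: Trace, rel_tol: float = 0.02
) -> ConvergenceReport:
    """Flag parameters whose posterior means disagree beyond ``rel_tol``."""
    if list(trace_a.samples.columns) != list(trace_b.samples.columns):
        raise ValueError("traces have different parameterizations")
    rows = []
    for col in trace_a.samples.columns:
        a = trace_a.samples[col].to_numpy()
        b = trace_b.samples[col].to_numpy()
        ma, mb = float(a.mean()), float(b.mean())
        scale = max(abs(ma), abs(mb), 1e-12)
        rel = abs(ma - mb) / scale
        rows.append(
            {"parameter": col, "mean_a": ma, "mean_b": mb, "rel_diff": rel,
             "ess_a": effective_sample_size(a), "ess_b": effective_sample_size(b),
             "flagged": rel > rel_tol}
        )
    table = pd.DataFrame(rows)
    return ConvergenceReport(table, passed=not table["flagged"].any())
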