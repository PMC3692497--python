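"""Synthetic data generators for every stage of the pipeline.

Sequence evolution follows the generative counterpart of the inference
model: root states drawn from the model's equilibrium frequencies, a
discrete-gamma rate category (or the invariant class) drawn once per
site, and states evolved down each branch with transition probabilities
exp(Q * rate * duration * category_rate).  Branch rates follow the
independent log-normal relaxed clock unless explicit per-branch
multipliers are given.  All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning, so each sub-generator is
reproducible in isolation.

The vertebrate dating fixture (:func:`make_vertebrate_scenario`) rebuilds the
12-species, 11-internal-node study layout: four tetrapods (Hs, Md, Gg,
Xt), three teleosts (Ol, Fr, Dr), three chondrichthyans (Sh, Ry, Cm) and
two outgroups (Ci, Dm).  Its node ages are the study's posterior means,
used here purely as simulation truth, and its calibration table is a
synthetic reconstruction of the described 19-constraint design (soft
min/max bounds outside the chondrichthyans from the standard fossil
compilation, a soft maximum near the root, and hard lower bounds at the
two chondrichthyan nodes), not a published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import JTT_ORDER, SubstitutionModel, build_jtt
from .seqio import Alignment, Calibration, SequenceRecord
from .trees import Node, PhyloTree

TIME_UNIT_MA = 100.0


@dataclass
class SimulationScenario:
    """Everything needed to evolve one alignment along a timetree.

    ``timetree`` carries node ages in Ma.  ``mean_rate`` is the median
    branch rate in substitutions/site per 100 My; per-branch rates are
    either drawn log-normally with drift ``sigma2`` or taken from
    ``rate_multipliers`` (child-node label -> multiplier on
    ``mean_rate``).
    """

    timetree: PhyloTree
    model: SubstitutionModel
    n_sites: int
    seed: int
    mean_rate: float = 0.08
    sigma2: float = 0.04
    rate_multipliers: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.timetree.validate_ages()
        if self.n_sites < 1 or self.mean_rate <= 0 or self.sigma2 < 0:
            raise ValueError("invalid scenario parameters")
        if self.rate_multipliers is not None:
            if any(m < 0 for m in self.rate_multipliers.values()):
                raise ValueError("rate multipliers must be non-negative")


def _branch_key(node: Node) -> str:
    return node.name if node.name else "|".join(sorted(node.tip_set()))


def simulate_alignment(
    scenario: SimulationScenario,
) -> tuple[Alignment, dict[str, float]]:
    """Evolve an alignment; returns it with the true branch lengths.

    Branch lengths (substitutions/site) are keyed by the child-node label
    of each branch.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    model = scenario.model
    tree = scenario.timetree
    n = scenario.n_sites

    # per-site rate class: invariant with prob p_inv, else a gamma category
    cats = rng.integers(0, model.n_categories, size=n)
    site_rates = model.category_rates[cats]
    if model.p_inv > 0:
        invariant = rng.random(n) < model.p_inv
        site_rates = np.where(invariant, 0.0, site_rates)

    pi = model.frequencies
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[id(root)] = rng.choice(len(pi), size=n, p=pi)

    true_lengths: dict[str, float] = {}
    seqs: dict[str, str] = {}
    aas = np.array(list(JTT_ORDER))
    for node in tree.preorder():
        if node.parent is None:
            continue
        child_age = node.age if node.age is not None else 0.0
        duration = (node.parent.age - child_age) / TIME_UNIT_MA
        if scenario.rate_multipliers is not None:
            rate = scenario.mean_rate * scenario.rate_multipliers.get(
                _branch_key(node), 1.0
            )
        else:
            rate = float(
                np.exp(rng.normal(np.log(scenario.mean_rate), np.sqrt(scenario.sigma2)))
            )
        blen = rate * duration
        true_lengths[_branch_key(node)] = blen
        parent_states = states[id(node.parent)]
        child_states = parent_states.copy()
        for r in np.unique(site_rates):
            mask = site_rates == r
            if r == 0.0 or blen == 0.0:
                continue
            P = model.transition_matrix(blen * r)
            cum = P.cumsum(axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child_states[mask] = (u[:, None] > rows).sum(axis=1)
        states[id(node)] = child_states
        if node.is_tip:
            seqs[node.name] = "".join(aas[child_states])
    records = [SequenceRecord(name, seqs[name]) for name in tree.tip_names()]
    return Alignment(records), true_lengths


# ---------------------------------------------------------------------------
# gene families for the orthology screen
# ---------------------------------------------------------------------------

#: species-tree ages (Ma) used for gene-family simulation
FAMILY_SPLITS = {
    "gnathostome": 454.0,  # human vs chondrichthyans
    "chimaera": 421.0,  # chimaera vs elasmobranchs
    "shark_ray": 306.0,
    "within_sharks": 150.0,
    "within_rays": 150.0,
}


def _family_species_tree() -> PhyloTree:
    """(Hs,(Cm,((Sc,Sq),(Le,Tc)))) with the divergence ages above."""
    root = Node("gnathostome", age=FAMILY_SPLITS["gnathostome"])
    hs = Node("Hs")
    chond = Node("chimaera", age=FAMILY_SPLITS["chimaera"])
    root.add_child(hs)
    root.add_child(chond)
    cm = Node("Cm")
    elasmo = Node("shark_ray", age=FAMILY_SPLITS["shark_ray"])
    chond.add_child(cm)
    chond.add_child(elasmo)
    sharks = Node("sharks", age=FAMILY_SPLITS["within_sharks"])
    rays = Node("rays", age=FAMILY_SPLITS["within_rays"])
    elasmo.add_child(sharks)
    elasmo.add_child(rays)
    for name, parent in (("Sc", sharks), ("Sq", sharks), ("Le", rays), ("Tc", rays)):
        parent.add_child(Node(name))
    return PhyloTree(root)


DATABASE_OF = {"Hs": "outgroup", "Sc": "sharks", "Sq": "sharks",
               "Le": "rays", "Tc": "rays"}


@dataclass
class GeneFamily:
    query: SequenceRecord  # the chimaera (Cm) sequence
    databases: dict[str, list[SequenceRecord]]  # outgroup / sharks / rays
    truth: dict[str, str]  # database sequence id -> "ortholog" | "paralog"


def make_gene_family(
    seed: int,
    n_sites: int = 300,
    mean_rate: float = 0.06,
    alpha: float = 0.6,
    sigma2: float = 0.02,
    outgroup_rate_multiplier: float = 2.5,
    include_outparalog: bool = False,
    duplication_age: float = 550.0,
    loss_pattern: dict[str, str] | None = None,
    model: SubstitutionModel | None = None,
) -> GeneFamily:
    """Simulate one gene family across the three screen databases.

    Branch rates combine log-normal drift (``sigma2``) with a faster
    outgroup lineage: the bony-vertebrate (human) branch runs at
    ``outgroup_rate_multiplier`` times the chondrichthyan rate, emulating
    the several-fold rate difference between tetrapods and cartilaginous
    fishes that gives the bit-score rule its margin in real data.

    Without a paralog, every database carries the true ortholog of the
    chimaera query.  With ``include_outparalog``, the family duplicated at
    ``duplication_age`` (predating the gnathostome split) into copies
    ``A`` (carrying the query) and ``B``; ``loss_pattern`` then says which
    copy each species retains (species label -> ``"A"``, ``"B"`` or
    ``"both"``; default keeps ``A`` everywhere and adds ``B`` nowhere).
    Retaining only ``B`` in the shark/ray databases is the hidden-paralogy
    trap the bit-score rule catches; retaining only ``B`` in the outgroup
    makes the outgroup look *more* distant and is invisible to the rule.
    """
    if model is None:
        model = build_jtt(alpha=alpha)
    species = _family_species_tree()
    if include_outparalog:
        if duplication_age <= FAMILY_SPLITS["gnathostome"]:
            raise ValueError("duplication must predate the gnathostome split")
        root = Node("duplication", age=duplication_age)
        copy_a = _family_species_tree().root
        copy_b = _family_species_tree().root
        _suffix_tips(copy_a, "_A")
        _suffix_tips(copy_b, "_B")
        root.add_child(copy_a)
        root.add_child(copy_b)
        tree = PhyloTree(root)
    else:
        tree = species
    rate_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    multipliers = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        key = _branch_key(node)
        mult = float(np.exp(rate_rng.normal(0.0, np.sqrt(sigma2))))
        if key.split("_")[0] == "Hs":
            mult *= outgroup_rate_multiplier
        multipliers[key] = mult
    scenario = SimulationScenario(
        timetree=tree, model=model, n_sites=n_sites, seed=seed,
        mean_rate=mean_rate, sigma2=sigma2, rate_multipliers=multipliers,
    )
    alignment, _ = simulate_alignment(scenario)
    seqs = {r.identifier: r.residues.replace("-", "") for r in alignment.records}

    loss_pattern = loss_pattern or {}
    databases: dict[str, list[SequenceRecord]] = {
        "outgroup": [], "sharks": [], "rays": []
    }
    truth: dict[str, str] = {}
    if not include_outparalog:
        query = SequenceRecord("Cm_query", seqs["Cm"])
        for sp, db in DATABASE_OF.items():
            databases[db].append(SequenceRecord(sp, seqs[sp]))
            truth[sp] = "ortholog"
    else:
        query = SequenceRecord("Cm_query", seqs["Cm_A"])
        for sp, db in DATABASE_OF.items():
            keep = loss_pattern.get(sp, "A")
            if keep in ("A", "both"):
                databases[db].append(SequenceRecord(f"{sp}_A", seqs[f"{sp}_A"]))
                truth[f"{sp}_A"] = "ortholog"
            if keep in ("B", "both"):
                databases[db].append(SequenceRecord(f"{sp}_B", seqs[f"{sp}_B"]))
                truth[f"{sp}_B"] = "paralog"
    for db, records in databases.items():
        if not records:
            raise ValueError(f"loss pattern left the {db} database empty")
    return GeneFamily(query, databases, truth)


def _suffix_tips(root: Node, suffix: str) -> None:
    stack = [root]
    while stack:
        n = stack.pop()
        if not n.children:
            n.name = n.name + suffix
        else:
            n.name = None
            stack.extend(n.children)


# ---------------------------------------------------------------------------
# the 12-taxon vertebrate dating scenario
# ---------------------------------------------------------------------------

#: posterior-mean node ages (Ma) used as simulation truth, by constraint set
VERTEBRATE_TRUTH_AGES = {
    "I": {"n1": 566, "n2": 547, "n3": 454, "n4": 418, "n5": 343, "n6": 319,
          "n7": 148, "n8": 157, "n9": 112, "n10": 421, "n11": 306},
    "II": {"n1": 566, "n2": 547, "n3": 454, "n4": 418, "n5": 343, "n6": 319,
           "n7": 148, "n8": 157, "n9": 112, "n10": 420, "n11": 261},
}


def vertebrate_topology(constraint_set: str = "I") -> PhyloTree:
    """The rooted 12-species study topology with truth ages attached.

    (((((((Hs,Md)n7,Gg)n6,Xt)n5,((Ol,Fr)n9,Dr)n8)n4,((Sh,Ry)n11,Cm)n10)n3,Ci)n2,Dm)n1
    """
    ages = VERTEBRATE_TRUTH_AGES[constraint_set]

    def internal(name: str, *children: Node) -> Node:
        node = Node(name, age=float(ages[name]))
        for c in children:
            node.add_child(c)
        return node

    tip = Node
    n7 = internal("n7", tip("Hs"), tip("Md"))
    n6 = internal("n6", n7, tip("Gg"))
    n5 = internal("n5", n6, tip("Xt"))
    n9 = internal("n9", tip("Ol"), tip("Fr"))
    n8 = internal("n8", n9, tip("Dr"))
    n4 = internal("n4", n5, n8)
    n11 = internal("n11", tip("Sh"), tip("Ry"))
    n10 = internal("n10", n11, tip("Cm"))
    n3 = internal("n3", n4, n10)
    n2 = internal("n2", n3, tip("Ci"))
    n1 = internal("n1", n2, tip("Dm"))
    return PhyloTree(n1)


def vertebrate_calibrations(constraint_set: str = "I") -> list[Calibration]:
    """Synthetic reconstruction of the 19-constraint calibration design."""
    t = vertebrate_topology(constraint_set)

    def clade(label: str) -> frozenset[str]:
        for node in t.postorder():
            if node.name == label:
                return node.tip_set()
        raise KeyError(label)

    node11_lower = 250.0 if constraint_set == "I" else 190.0
    return [
        Calibration(clade("n1"), 531.5, 581.0, "soft"),
        Calibration(clade("n2"), None, 581.0, "soft-upper"),
        Calibration(clade("n3"), 421.75, 462.5, "soft"),
        Calibration(clade("n4"), 416.0, 421.75, "soft"),
        Calibration(clade("n5"), 330.4, 350.1, "soft"),
        Calibration(clade("n6"), 312.3, 330.4, "soft"),
        Calibration(clade("n7"), 124.6, 171.2, "soft"),
        Calibration(clade("n8"), 149.85, 165.2, "soft"),
        Calibration(clade("n9"), 96.9, 150.9, "soft"),
        Calibration(clade("n10"), 410.0, None, "hard-lower"),
        Calibration(clade("n11"), node11_lower, None, "hard-lower"),
    ]


def make_vertebrate_scenario(
    constraint_set: str = "I",
    n_sites: int = 2000,
    seed: int = 0,
    alpha: float = 0.55,
    mean_rate: float = 0.08,
    sigma2: float = 0.04,
) -> tuple[PhyloTree, list[Calibration], Alignment, SimulationScenario]:
    """Timetree + calibrations + simulated alignment for the dating study.

    The alignment evolves under JTT+Gamma with independent log-normal
    branch rates; defaults (2000 sites, alpha 0.55, median rate 0.08
    substitutions/site/100 My, drift 0.04) mirror the scale of the real
    20-gene concatenation (2973 sites, per-gene alpha mostly 0.3-1.0,
    sub-1 root-to-tip expected divergence).
    """
    timetree = vertebrate_topology(constraint_set)
    calibrations = vertebrate_calibrations(constraint_set)
    model = build_jtt(alpha=alpha)
    scenario = SimulationScenario(
        timetree=timetree, model=model, n_sites=n_sites, seed=seed,
        mean_rate=mean_rate, sigma2=sigma2,
    )
    alignment, _ = simulate_alignment(scenario)
    return timetree, calibrations, alignment, scenario
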