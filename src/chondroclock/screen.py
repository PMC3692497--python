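"""Preliminary orthology screen for chimaera query genes.

The screen mirrors a three-database homology search: each query peptide is
scored against an outgroup database (human), a shark database and a
ray/skate database by optimal local alignment (Smith-Waterman, affine
gaps, BLOSUM62 by default), converted to bits with gapped Karlin-Altschul
constants.  A gene passes the preliminary orthology rule iff its best
outgroup score S_co is strictly smaller than both ingroup best scores
(S_cs, sharks; S_cr, rays/skates) -- the ortholog must look closer to the
ingroups than to the outgroup.  Genes hitting an excessive number of
database copies (> 500 by default) are discarded as members of massively
expanded families.  Gap convention: a gap of length k costs
open + k * extend (the BLAST convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import Alignment, SequenceRecord

#: gapped Karlin-Altschul constants for BLOSUM62 with gap open 11 / extend 1
DEFAULT_LAMBDA = 0.267
DEFAULT_KAPPA = 0.041
DEFAULT_BIT_THRESHOLD = 40.0  # reporting threshold for counting hits


@dataclass(frozen=True)
class ScoreTriple:
    gene: str
    s_co: float  # bits, best hit vs outgroup (human)
    s_cs: float  # bits, best hit vs sharks
    s_cr: float  # bits, best hit vs rays/skates


@dataclass(frozen=True)
class ScreenDecision:
    gene: str
    passed: bool
    reason: str  # passed | outgroup-score-not-smaller | copy-number-exceeded


def _make_aligner(scoring: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring)
    # BLAST convention: gap length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def raw_local_score(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Optimal local-alignment raw score (floored at 0: the empty alignment)."""
    if not query.residues or not subject.residues:
        raise ValueError("empty sequence")
    aligner = _make_aligner(scoring, gap_open, gap_extend)
    q = query.residues.replace("-", "X")
    s = subject.residues.replace("-", "X")
    return max(float(aligner.score(q, s)), 0.0)


def bits_from_raw(raw: float, lam: float = DEFAULT_LAMBDA, kappa: float = DEFAULT_KAPPA) -> float:
    """Karlin-Altschul normalized score S' = (lambda*S - ln kappa) / ln 2."""
    return (lam * raw - math.log(kappa)) / math.log(2.0)


def local_align_bitscore(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    lam: float = DEFAULT_LAMBDA,
    kappa: float = DEFAULT_KAPPA,
) -> float:
    """Bit score of the optimal local alignment; symmetric in its arguments."""
    return bits_from_raw(
        raw_local_score(query, subject, scoring, gap_open, gap_extend), lam, kappa
    )


def best_hit_score(
    query: SequenceRecord,
    database: list[SequenceRecord],
    scoring: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    lam: float = DEFAULT_LAMBDA,
    kappa: float = DEFAULT_KAPPA,
    bit_threshold: float = DEFAULT_BIT_THRESHOLD,
) -> tuple[float, str, int]:
    """Best bit score over a database.

    Returns ``(bits, subject_id, hit_count)`` where ``hit_count`` is the
    number of subjects at or above the reporting threshold.
    """
    if not database:
        raise ValueError("empty database")
    best_bits, best_id, hits = -math.inf, None, 0
    for subject in database:
        bits = local_align_bitscore(
            query, subject, scoring, gap_open, gap_extend, lam, kappa
        )
        if bits >= bit_threshold:
            hits += 1
        if bits > best_bits:
            best_bits, best_id = bits, subject.identifier
    return best_bits, best_id, hits


def preliminary_orthology_rule(triple: ScoreTriple) -> ScreenDecision:
    """Pass iff S_co < S_cs and S_co < S_cr (strict; ties fail)."""
    for v in (triple.s_co, triple.s_cs, triple.s_cr):
        if v is None or not math.isfinite(v):
            raise ValueError(f"gene {triple.gene!r}: missing score")
    if triple.s_co < triple.s_cs and triple.s_co < triple.s_cr:
        return ScreenDecision(triple.gene, True, "passed")
    return ScreenDecision(triple.gene, False, "outgroup-score-not-smaller")


def copy_number_filter(gene: str, hit_count: int, threshold: int = 500) -> ScreenDecision:
    """Fail iff hit_count exceeds the copy-number threshold (strict >)."""
    if hit_count < 0:
        raise ValueError("negative hit count")
    if hit_count > threshold:
        return ScreenDecision(gene, False, "copy-number-exceeded")
    return ScreenDecision(gene, True, "passed")


def screen_gene(
    gene: str,
    query: SequenceRecord,
    outgroup_db: list[SequenceRecord],
    shark_db: list[SequenceRecord],
    ray_db: list[SequenceRecord],
    copy_threshold: int = 500,
    **align_kwargs,
) -> ScreenDecision:
    """Full per-gene screen: copy-number filter, then the bit-score rule."""
    s_co, _, n_co = best_hit_score(query, outgroup_db, **align_kwargs)
    s_cs, _, n_cs = best_hit_score(query, shark_db, **align_kwargs)
    s_cr, _, n_cr = best_hit_score(query, ray_db, **align_kwargs)
    copies = copy_number_filter(gene, max(n_co, n_cs, n_cr), copy_threshold)
    if not copies.passed:
        return copies
    return preliminary_orthology_rule(ScoreTriple(gene, s_co, s_cs, s_cr))


def read_score_table(path_or_handle) -> list[ScoreTriple]:
    """Read precomputed bit-score triples from a TSV.

    Columns: gene, S_co, S_cs, S_cr.  This bypasses the internal aligner
    for users with existing homology-search output.
    """
    import pandas as pd

    df = pd.read_csv(path_or_handle, sep="\t")
    required = {"gene", "S_co", "S_cs", "S_cr"}
    if not required <= set(df.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    return [
        ScoreTriple(str(r.gene), float(r.S_co), float(r.S_cs), float(r.S_cr))
        for r in df.itertuples()
    ]


def trim_alignment_ends(
    alignment: Alignment,
    reference_taxa,
    window: int = 20,
    min_occupancy: float = 0.9,
) -> Alignment:
    """Truncate gappy alignment ends, judged against the reference taxa.

    Leading columns are removed up to the first run of ``window``
    consecutive columns that each have at least ``min_occupancy``
    non-missing fraction among ``reference_taxa``; symmetric at the other
    end.  Interior columns are never removed.
    """
    reference_taxa = set(reference_taxa)
    taxa = set(alignment.taxa)
    if not reference_taxa <= taxa:
        raise ValueError(f"reference taxa not in alignment: {sorted(reference_taxa - taxa)}")
    missing = alignment.missing_set()
    refs = [r for r in alignment.records if r.identifier in reference_taxa]
    n = alignment.n_sites
    occ = [
        sum(1 for r in refs if r.residues[j] not in missing) / len(refs)
        for j in range(n)
    ]
    dense = [o >= min_occupancy for o in occ]

    def first_window(flags) -> int | None:
        run = 0
        for j, ok in enumerate(flags):
            run = run + 1 if ok else 0
            if run >= window:
                return j - window + 1
        return None

    start = first_window(dense)
    if start is None:
        raise ValueError("alignment empty after trimming")
    stop_rev = first_window(dense[::-1])
    stop = n - stop_rev
    return alignment.select_columns(list(range(start, stop)))


def drop_divergent_teleost_copy(
    candidates: dict[str, str],
    consensus: str,
    model,
) -> str:
    """Between two teleost duplicate candidates, keep the less divergent one.

    ``candidates`` maps copy name -> aligned sequence; ``consensus`` is an
    aligned non-teleost reference sequence.  Returns the retained copy
    name (smaller ML distance to the reference; ties keep the
    lexicographically first name).  This realizes the exclusion of the
    more divergent duplicate that arose in the teleost-specific genome
    duplication; it is an explicit step, never run automatically.
    """
    from .likelihood import pairwise_ml_distance

    if len(candidates) < 2:
        raise ValueError("need at least two candidate copies")
    scored = sorted(
        (pairwise_ml_distance(seq, consensus, model), name)
        for name, seq in candidates.items()
    )
    return scored[0][1]
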