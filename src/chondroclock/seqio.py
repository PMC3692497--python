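"""Sequence, alignment and calibration I/O shared by all pipeline stages.

Sequences are amino-acid (20 states + ``-`` gap + ``X`` unknown) or
nucleotide (ACGT + ``-`` + ``N``).  Alignment column intervals are 0-based,
half-open throughout.  Calibration bounds are in Ma (million years before
present) at every user-facing boundary; the dating engine converts to its
internal 100-My time unit.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_MISSING = "-X"
NUCLEOTIDES = "ACGT"
NT_MISSING = "-N"

_AA_SET = frozenset(AMINO_ACIDS + AA_MISSING)
_NT_SET = frozenset(NUCLEOTIDES + NT_MISSING)


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; residues are upper-case."""

    identifier: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length sequence records plus an optional gene partition map.

    ``partitions`` maps gene name -> (start, stop) half-open column
    interval; intervals must tile a prefix of the columns without overlap.
    """

    records: list[SequenceRecord]
    alphabet: str = "amino-acid"  # or "nucleotide"
    partitions: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        n = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != n:
                raise ValueError(
                    f"unequal lengths: {rec.identifier} has {len(rec.residues)}, "
                    f"expected {n}"
                )
        names = [r.identifier for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate record identifiers in alignment")
        if self.partitions is not None:
            pos = 0
            for gene, (start, stop) in self.partitions.items():
                if start != pos or stop <= start:
                    raise ValueError(f"partition {gene!r} does not tile columns")
                pos = stop
            if pos > n:
                raise ValueError("partitions exceed alignment length")

    @property
    def n_sites(self) -> int:
        return len(self.records[0].residues)

    @property
    def taxa(self) -> list[str]:
        return [r.identifier for r in self.records]

    def missing_set(self) -> frozenset[str]:
        return frozenset(AA_MISSING if self.alphabet == "amino-acid" else NT_MISSING)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def select_columns(self, cols: list[int]) -> "Alignment":
        recs = [
            SequenceRecord(r.identifier, "".join(r.residues[j] for j in cols))
            for r in self.records
        ]
        return Alignment(recs, alphabet=self.alphabet)


def detect_alphabet(records: list[SequenceRecord]) -> str:
    chars = set()
    for r in records:
        chars.update(r.residues)
    if chars <= _NT_SET:
        return "nucleotide"
    if chars <= _AA_SET:
        return "amino-acid"
    bad = sorted(chars - _AA_SET)
    raise ValueError(f"illegal characters {bad} (not amino-acid or nucleotide)")


def read_fasta(path_or_handle) -> list[SequenceRecord]:
    """Read FASTA into records; residues are upper-cased and validated.

    Raises on empty input, duplicate identifiers, or illegal characters
    (the error names the offending sequence and position).
    """
    if isinstance(path_or_handle, str):
        handle = open(path_or_handle)
        close = True
    else:
        handle, close = path_or_handle, False
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate identifier {rec.id!r}")
            seen.add(rec.id)
            residues = str(rec.seq).upper()
            if not residues:
                raise ValueError(f"empty sequence for {rec.id!r}")
            for pos, ch in enumerate(residues):
                if ch not in _AA_SET and ch not in _NT_SET:
                    raise ValueError(
                        f"illegal character {ch!r} at position {pos} in {rec.id!r}"
                    )
            records.append(SequenceRecord(rec.id, residues))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("no records")
    return records


def read_fasta_text(text: str) -> list[SequenceRecord]:
    return read_fasta(_io.StringIO(text))


def write_fasta(records: list[SequenceRecord], path_or_handle) -> None:
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            _write_fasta(records, fh)
    else:
        _write_fasta(records, path_or_handle)


def _write_fasta(records, fh) -> None:
    for rec in records:
        fh.write(f">{rec.identifier}\n")
        for i in range(0, len(rec.residues), 70):
            fh.write(rec.residues[i : i + 70] + "\n")


def read_alignment(path_or_handle, alphabet: str | None = None) -> Alignment:
    records = read_fasta(path_or_handle)
    if alphabet is None:
        alphabet = detect_alphabet(records)
    return Alignment(records, alphabet=alphabet)


def concatenate(
    alignments: list[Alignment],
    gene_names: list[str] | None = None,
    pad_missing: bool = False,
) -> Alignment:
    """Concatenate per-gene alignments into one supermatrix.

    All inputs must share an identical taxon set; a mismatch raises an
    error listing the symmetric difference.  With ``pad_missing=True``,
    taxa absent from a gene are filled with gaps instead (the escape hatch
    for datasets that keep a gene missing one core species).
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if gene_names is None:
        gene_names = [f"gene{i + 1}" for i in range(len(alignments))]
    if len(gene_names) != len(alignments):
        raise ValueError("gene_names length mismatch")

    if pad_missing:
        taxa: list[str] = []
        for aln in alignments:
            for t in aln.taxa:
                if t not in taxa:
                    taxa.append(t)
    else:
        taxa = alignments[0].taxa
        ref = set(taxa)
        for aln, gene in zip(alignments[1:], gene_names[1:]):
            other = set(aln.taxa)
            if other != ref:
                diff = sorted(ref.symmetric_difference(other))
                raise ValueError(
                    f"taxon sets differ at {gene!r}; symmetric difference: {diff}"
                )

    parts: dict[str, tuple[int, int]] = {}
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for aln, gene in zip(alignments, gene_names):
        n = aln.n_sites
        gap = "-" * n
        bytaxon = {r.identifier: r.residues for r in aln.records}
        for t in taxa:
            pieces[t].append(bytaxon.get(t, gap))
        parts[gene] = (pos, pos + n)
        pos += n
    records = [SequenceRecord(t, "".join(pieces[t])) for t in taxa]
    return Alignment(records, alphabet=alignments[0].alphabet, partitions=parts)


def split_by_partition(alignment: Alignment) -> dict[str, Alignment]:
    """Inverse of :func:`concatenate` for the partitioned prefix."""
    if not alignment.partitions:
        raise ValueError("alignment carries no partition map")
    out = {}
    for gene, (start, stop) in alignment.partitions.items():
        recs = [
            SequenceRecord(r.identifier, r.residues[start:stop])
            for r in alignment.records
        ]
        out[gene] = Alignment(recs, alphabet=alignment.alphabet)
    return out


def complete_deletion(alignment: Alignment) -> Alignment:
    """Keep only columns where no record has a gap or unknown character."""
    missing = alignment.missing_set()
    keep = [
        j
        for j in range(alignment.n_sites)
        if not any(r.residues[j] in missing for r in alignment.records)
    ]
    return alignment.select_columns(keep)


@dataclass(frozen=True)
class Calibration:
    """A fossil time constraint on the clade spanned by ``clade_tips``.

    ``style`` is ``soft`` (min+max with small tail probabilities outside),
    ``soft-upper`` (max only), or ``hard-lower`` (strict minimum, no max).
    Bounds in Ma.
    """

    clade_tips: frozenset[str]
    lower_Ma: float | None = None
    upper_Ma: float | None = None
    style: str = "soft"

    def __post_init__(self) -> None:
        if self.style not in ("soft", "soft-upper", "hard-lower"):
            raise ValueError(f"unknown calibration style {self.style!r}")
        if self.style == "soft" and not (
            self.lower_Ma is not None
            and self.upper_Ma is not None
            and self.lower_Ma < self.upper_Ma
        ):
            raise ValueError("soft calibration requires lower < upper")
        if self.style == "soft-upper" and self.upper_Ma is None:
            raise ValueError("soft-upper calibration requires an upper bound")
        if self.style == "hard-lower" and (
            self.lower_Ma is None or self.upper_Ma is not None
        ):
            raise ValueError("hard-lower calibration takes a lower bound only")


def read_calibration_table(path_or_handle) -> list[Calibration]:
    """Read a TSV with columns clade_tips, lower_Ma, upper_Ma, style.

    ``clade_tips`` is a comma-separated tip-label list; empty cells mean
    an absent bound.
    """
    df = pd.read_csv(path_or_handle, sep="\t", dtype=str)
    required = {"clade_tips", "lower_Ma", "upper_Ma", "style"}
    if not required <= set(df.columns):
        raise ValueError(f"calibration table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        lower = None if pd.isna(row["lower_Ma"]) or row["lower_Ma"] == "" else float(row["lower_Ma"])
        upper = None if pd.isna(row["upper_Ma"]) or row["upper_Ma"] == "" else float(row["upper_Ma"])
        tips = frozenset(t.strip() for t in row["clade_tips"].split(",") if t.strip())
        out.append(Calibration(tips, lower, upper, row["style"].strip()))
    return out


def write_calibration_table(calibrations: list[Calibration], path_or_handle) -> None:
    rows = [
        {
            "clade_tips": ",".join(sorted(c.clade_tips)),
            "lower_Ma": "" if c.lower_Ma is None else c.lower_Ma,
            "upper_Ma": "" if c.upper_Ma is None else c.upper_Ma,
            "style": c.style,
        }
        for c in calibrations
    ]
    pd.DataFrame(rows).to_csv(path_or_handle, sep="\t", index=False)
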