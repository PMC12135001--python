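"""Core sequence records, FASTA / tabular I/O and pairwise global alignment.

Every downstream stage (divergence calling, primer design, in silico PCR)
works on the plain-DNA records defined here.  Coordinates throughout the
package are 0-based, half-open; strand is encoded as ``"+"`` / ``"-"``.

Only the unambiguous DNA alphabet plus ``N`` is accepted: the fixed
X-Y difference caller needs unambiguous bases, so IUPAC ambiguity codes
other than ``N`` are rejected at parse time with a clear error rather
than silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FASTA_WRAP = 60


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """A candidate sex-linked gene: one Y copy, >=1 X haplotype copies,
    plus the metadata the selection filters consume.

    ``ds`` is ``None`` until estimated; ``float("nan")`` flags a
    saturated (uncorrectable) divergence.
    """

    gene_id: str
    y_sequence: str
    x_sequences: list[SeqRecord] = field(default_factory=list)
    stratum: int = 0
    y_expressed: bool = True
    intron_length_bp: int = 0
    ds: float | None = None

    def __post_init__(self) -> None:
        if len(self.y_sequence) < 3:
            raise ValueError(f"gene {self.gene_id}: coding sequence shorter than one codon")
        for x in self.x_sequences:
            if len(x.sequence) < 3:
                raise ValueError(f"gene {self.gene_id}: X copy {x.id} shorter than one codon")
        if self.intron_length_bp < 0:
            raise ValueError(f"gene {self.gene_id}: negative intron length")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment; gap character is ``-``."""

    seq_a_aligned: str
    seq_b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a_aligned) != len(self.seq_b_aligned):
            raise ValueError("aligned strings must have identical length")

    @property
    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.seq_a_aligned, self.seq_b_aligned)


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase ``raw`` and validate the {A,C,G,T,N} alphabet.

    ``U`` and IUPAC ambiguity codes other than N are rejected.
    """
    seq = raw.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"{context}: illegal characters {sorted(bad)} (only A,C,G,T,N accepted)"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    seq = normalize_sequence(sequence, context="reverse_complement input")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA file.

    Line wrapping is removed, sequences are uppercased and validated,
    record order is preserved.  Malformed headers or illegal sequence
    characters raise :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    current_desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        records.append(SeqRecord(id=current_id, sequence=seq, description=current_desc))

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                current_id = parts[0]
                current_desc = parts[1] if len(parts) > 1 else ""
                if current_id in seen:
                    raise FastaParseError(
                        f"{path}: duplicate record id {current_id!r} at line {lineno}"
                    )
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                try:
                    chunks.append(normalize_sequence(line, context=f"line {lineno}"))
                except SequenceAlphabetError as exc:
                    raise FastaParseError(f"{path}: {exc}") from exc
        flush()
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), FASTA_WRAP):
                fh.write(rec.sequence[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# Gene metadata table


def read_gene_metadata(path: str | Path) -> dict[str, dict]:
    """Read the tab-separated gene metadata table.

    Expected header: ``gene_id  stratum  y_expressed  intron_length_bp``.
    Returns ``{gene_id: {"stratum": int, "y_expressed": bool,
    "intron_length_bp": int}}``.
    """
    path = Path(path)
    expected = ["gene_id", "stratum", "y_expressed", "intron_length_bp"]
    out: dict[str, dict] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: wrong field count at line {lineno}")
            gene_id, stratum, y_expr, intron = fields
            if y_expr not in ("true", "false"):
                raise ValueError(
                    f"{path}: y_expressed must be true/false at line {lineno}, got {y_expr!r}"
                )
            out[gene_id] = {
                "stratum": int(stratum),
                "y_expressed": y_expr == "true",
                "intron_length_bp": int(intron),
            }
    return out


def write_gene_metadata(rows: Iterable[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tstratum\ty_expressed\tintron_length_bp\n")
        for g in rows:
            fh.write(
                f"{g.gene_id}\t{g.stratum}\t{'true' if g.y_expressed else 'false'}"
                f"\t{g.intron_length_bp}\n"
            )


# ---------------------------------------------------------------------------
# Global alignment


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring; a gap of length L costs ``gap_open + L * gap_extend``.

    Defaults are NCBI-megablast-like.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = AlignmentScoring()


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # PairwiseAligner charges open_gap_score for the first gap position,
    # so open+extend there reproduces open + L*extend for a length-L gap.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_global(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global alignment of two DNA strings under affine-gap scoring.

    The highest-scoring alignment is returned; among co-optimal
    alignments the aligner's first traceback is taken, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("align_global requires two non-empty sequences")
    a = normalize_sequence(a, context="align_global sequence a")
    b = normalize_sequence(b, context="align_global sequence b")
    aligner = _make_aligner(scoring)
    alignment = next(iter(aligner.align(a, b)))
    return PairwiseAlignment(
        seq_a_aligned=str(alignment[0]),
        seq_b_aligned=str(alignment[1]),
        score=float(alignment.score),
    )
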