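"""Codon-level synonymous divergence (dS), gene-selection filters, and
fixed X-Y difference calling.

dS between the X and Y copy of a sex-linked gene dates the recombination
arrest of the stratum the gene sits in: the older the stratum, the larger
dS, and the more X-Y differences are shared across cultivars.  The
estimator here is Nei-Gojobori (1986): per-codon counting of synonymous
and nonsynonymous sites, pathway-averaged difference counting for
multi-hit codons, and a Jukes-Cantor multiple-hit correction

    dS = -(3/4) * ln(1 - (4/3) * pS),

undefined ("saturated") when pS >= 3/4.  Mutational pathways passing
through a stop codon are excluded from the average; if every shortest
pathway is blocked, all pathways are used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .sequence_model import (
    AlignmentScoring,
    DEFAULT_SCORING,
    GeneRecord,
    SeqRecord,
    align_global,
)

_BASES = "ACGT"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)

SATURATION_PS = 0.75


class CodingSequenceError(ValueError):
    """Raised for stop codons, frame problems, or ambiguous codons."""


@dataclass(frozen=True)
class DivergenceEstimate:
    """Nei-Gojobori site/difference counts and corrected rates.

    ``ds`` / ``dn`` are ``nan`` when the Jukes-Cantor logarithm is
    undefined; the ``*_saturated`` flags make that state explicit.
    """

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int

    @property
    def ps(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites > 0 else 0.0

    @property
    def pn(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites > 0 else 0.0

    @property
    def ds_saturated(self) -> bool:
        return self.ps >= SATURATION_PS

    @property
    def dn_saturated(self) -> bool:
        return self.pn >= SATURATION_PS

    @property
    def ds(self) -> float:
        return _jukes_cantor(self.ps)

    @property
    def dn(self) -> float:
        return _jukes_cantor(self.pn)


def _jukes_cantor(p: float) -> float:
    if p >= SATURATION_PS:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise CodingSequenceError(f"not an unambiguous codon: {codon!r}")
    if codon in _STOP_CODONS:
        raise CodingSequenceError(f"stop codon {codon} not allowed")


@lru_cache(maxsize=None)
def count_codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    Each position contributes the fraction of its 3 possible single-base
    changes that leave the amino acid unchanged (changes to stop codons
    count as nonsynonymous); the two counts always sum to 3.
    """
    _check_codon(codon)
    aa = _CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TO_AA.get(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def count_codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous / nonsynonymous differences between
    two codons, all shortest mutational pathways weighted equally.
    """
    _check_codon(codon_a)
    _check_codon(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    pathways: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOP_CODONS:
                through_stop = True
            aa_before = _CODON_TO_AA.get(current)
            aa_after = _CODON_TO_AA.get(nxt)
            if aa_before is not None and aa_before == aa_after:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        (blocked if through_stop else pathways).append((syn, nonsyn))
    usable = pathways or blocked
    syn = sum(p[0] for p in usable) / len(usable)
    nonsyn = sum(p[1] for p in usable) / len(usable)
    return syn, nonsyn


def _codons(seq: str) -> list[str]:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return [trimmed[i : i + 3] for i in range(0, len(trimmed), 3)]


def nei_gojobori_ds(cds_a: str, cds_b: str) -> DivergenceEstimate:
    """NG86 divergence between two codon-aligned coding sequences.

    Inputs must have equal length (gap characters allowed); codon pairs
    containing a gap or N in either sequence are dropped pairwise.
    Trailing incomplete codons are trimmed; a premature stop codon in
    either sequence raises :class:`CodingSequenceError` (a stop in the
    final codon position of both is treated as terminal and skipped).
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise CodingSequenceError(
            f"codon-aligned sequences must have equal length ({len(a)} != {len(b)})"
        )
    codons_a, codons_b = _codons(a), _codons(b)
    n_codons = len(codons_a)

    syn_sites_a = syn_sites_b = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    used = 0
    for idx, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        is_last = idx == n_codons - 1
        if ca in _STOP_CODONS or cb in _STOP_CODONS:
            if is_last:
                continue  # terminal stop codon: not compared
            raise CodingSequenceError(f"premature stop codon at codon {idx}")
        sa, _ = count_codon_sites(ca)
        sb, _ = count_codon_sites(cb)
        syn_sites_a += sa
        syn_sites_b += sb
        sd, nd = count_codon_diffs(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd
        used += 1
    if used == 0:
        raise CodingSequenceError("no comparable codons after filtering")
    syn_sites = (syn_sites_a + syn_sites_b) / 2.0
    return DivergenceEstimate(
        syn_sites=syn_sites,
        nonsyn_sites=3.0 * used - syn_sites,
        syn_diffs=syn_diffs,
        nonsyn_diffs=nonsyn_diffs,
        n_codons=used,
    )


# ---------------------------------------------------------------------------
# Fixed X-Y differences


@dataclass(frozen=True)
class FixedDiffSite:
    """An alignment column where every X haplotype carries the same
    unambiguous base and the Y copy carries a different one.

    ``column_index`` is 0-based in the Y coordinate frame.
    """

    gene_id: str
    column_index: int
    y_allele: str
    x_allele: str

    def __post_init__(self) -> None:
        if self.y_allele == self.x_allele:
            raise ValueError("fixed difference requires distinct alleles")
        for allele in (self.y_allele, self.x_allele):
            if allele not in "ACGT":
                raise ValueError(f"allele must be unambiguous, got {allele!r}")


def call_fixed_differences(
    y: SeqRecord,
    x_set: list[SeqRecord],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    gene_id: str | None = None,
) -> list[FixedDiffSite]:
    """Call sites fixed between the Y copy and all supplied X haplotypes.

    Each X haplotype is globally aligned to Y and its bases projected
    onto Y coordinates.  A site is reported iff every X has the same
    ungapped, unambiguous base there and that base differs from Y.
    Using X copies from several cultivars raises the odds that reported
    sites are shared across populations; fewer than 3 triggers a warning.
    """
    if not x_set:
        raise ValueError("call_fixed_differences requires at least one X haplotype")
    if len(x_set) < 3:
        warnings.warn(
            f"only {len(x_set)} X haplotype(s) supplied; 3+ cultivars are "
            "recommended to call differences fixed across populations",
            stacklevel=2,
        )
    gene_id = gene_id or y.id
    # per-X base at each Y position ("-" where X is gapped)
    profiles: list[list[str]] = []
    for x in x_set:
        aln = align_global(y.sequence, x.sequence, scoring)
        profile = []
        for cy, cx in zip(aln.seq_a_aligned, aln.seq_b_aligned):
            if cy != "-":
                profile.append(cx)
        assert len(profile) == len(y.sequence)
        profiles.append(profile)

    sites: list[FixedDiffSite] = []
    for pos, y_base in enumerate(y.sequence):
        if y_base not in "ACGT":
            continue
        x_alleles = {p[pos] for p in profiles}
        if len(x_alleles) != 1:
            continue
        (x_base,) = x_alleles
        if x_base in "ACGT" and x_base != y_base:
            sites.append(
                FixedDiffSite(
                    gene_id=gene_id, column_index=pos, y_allele=y_base, x_allele=x_base
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Candidate-gene selection


def select_candidate_genes(
    genes: list[GeneRecord], top_k: int = 20, min_intron_bp: int = 300
) -> list[GeneRecord]:
    """Apply the marker-gene selection filters.

    In order: keep genes whose Y copy is still expressed; keep only the
    oldest stratum present in the input (minimum stratum label); rank the
    survivors by dS (descending, saturated estimates last, ties broken by
    gene_id) and keep the ``top_k`` most divergent; finally drop genes
    whose intron is shorter than ``min_intron_bp`` (short introns leave
    too little room for intron-spanning genomic amplicons).
    """
    for g in genes:
        if g.ds is None:
            raise ValueError(f"gene {g.gene_id}: ds has not been estimated")
        if g.stratum is None or g.intron_length_bp is None or g.y_expressed is None:
            raise ValueError(f"gene {g.gene_id}: missing selection metadata")
    if not genes:
        return []
    oldest = min(g.stratum for g in genes)
    survivors = [g for g in genes if g.y_expressed and g.stratum == oldest]

    def rank_key(g: GeneRecord) -> tuple:
        saturated = math.isnan(g.ds)
        return (saturated, -(0.0 if saturated else g.ds), g.gene_id)

    ranked = sorted(survivors, key=rank_key)[: max(top_k, 0)]
    return [g for g in ranked if g.intron_length_bp >= min_intron_bp]
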