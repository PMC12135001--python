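"""Mismatch-tolerant in silico PCR on genome templates.

A primer binds where the template matches it with at most
``max_mismatch`` mismatches AND matches the 3'-terminal
``three_prime_exact_nt`` bases exactly — the polymerase extends from the
3' end, so terminal mismatches abort extension.  This 3'-exact rule is
what lets a Y-anchored primer reject the X allele while tolerating a
couple of incidental mismatches elsewhere.  Amplicons are predicted by
pairing plus-strand forward sites with downstream minus-strand reverse
sites, and per-genome validation checks that a Y-specific pair amplifies
exactly once in males and never in females.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .primer_engine import MultiplexPanel, Primer, PrimerPair
from .sequence_model import SeqRecord, normalize_sequence, reverse_complement


@dataclass(frozen=True)
class InSilicoSettings:
    """Binding / product-size tolerances for the in silico PCR scan."""

    max_mismatch: int = 2
    three_prime_exact_nt: int = 3
    amp_max: int = 3000


DEFAULT_SETTINGS = InSilicoSettings()


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on a template; coordinates 0-based half-open
    on the plus strand.  On the minus strand the primer's 3' end maps to
    ``start``."""

    template_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    n_mismatches: int
    three_prime_mismatch: bool = False


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, spanning both primer footprints."""

    template_id: str
    start: int
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeAmplification:
    genome_id: str
    expected_sex: str  # male | female | unknown
    n_amplicons: int
    sizes: tuple[int, ...]


@dataclass(frozen=True)
class MarkerValidation:
    """Per-genome amplification summary for one primer pair.

    A y_specific pair is valid iff every male genome yields exactly one
    amplicon and every female genome none; a control pair is valid iff
    every genome yields exactly one.
    """

    primer_pair_id: str
    target_type: str
    entries: tuple[GenomeAmplification, ...]

    @property
    def valid(self) -> bool:
        for e in self.entries:
            if self.target_type == "y_specific":
                if e.expected_sex == "male" and e.n_amplicons != 1:
                    return False
                if e.expected_sex == "female" and e.n_amplicons != 0:
                    return False
            else:
                if e.n_amplicons != 1:
                    return False
        return True


def _primer_seq(primer) -> str:
    return primer.sequence if isinstance(primer, Primer) else normalize_sequence(primer)


def _scan(template: np.ndarray, probe: str) -> np.ndarray:
    """Mismatch counts of ``probe`` against every window of ``template``
    (uint8 arrays; N never matches)."""
    m = len(probe)
    windows = np.lib.stride_tricks.sliding_window_view(template, m)
    parr = np.frombuffer(probe.encode(), dtype=np.uint8)
    neq = windows != parr
    # template N counts as mismatch even against a (disallowed) probe N
    neq |= windows == ord("N")
    return neq


def find_binding_sites(
    primer,
    template: SeqRecord,
    max_mismatch: int = DEFAULT_SETTINGS.max_mismatch,
    three_prime_exact_nt: int = DEFAULT_SETTINGS.three_prime_exact_nt,
) -> list[BindingSite]:
    """All binding sites of ``primer`` on both strands of ``template``.

    A site needs <= ``max_mismatch`` mismatches overall and zero in the
    3'-terminal ``three_prime_exact_nt`` bases.  Primers containing N are
    rejected; template N counts as a mismatch.
    """
    pseq = _primer_seq(primer)
    if "N" in pseq:
        raise ValueError("degenerate (N-containing) primers are not supported")
    m = len(pseq)
    if len(template.sequence) < m:
        return []
    tarr = np.frombuffer(template.sequence.encode(), dtype=np.uint8)
    k = min(three_prime_exact_nt, m)
    sites: list[BindingSite] = []

    # plus strand: primer 3' end at window end
    neq = _scan(tarr, pseq)
    mism = neq.sum(axis=1)
    zone_ok = ~neq[:, m - k :].any(axis=1) if k else np.ones(len(neq), dtype=bool)
    for pos in np.nonzero((mism <= max_mismatch) & zone_ok)[0]:
        sites.append(
            BindingSite(
                template_id=template.id,
                start=int(pos),
                end=int(pos) + m,
                strand="+",
                n_mismatches=int(mism[pos]),
            )
        )

    # minus strand: the template substring equals revcomp(primer); the
    # primer's 3'-terminal bases map to the window start
    neq = _scan(tarr, reverse_complement(pseq))
    mism = neq.sum(axis=1)
    zone_ok = ~neq[:, :k].any(axis=1) if k else np.ones(len(neq), dtype=bool)
    for pos in np.nonzero((mism <= max_mismatch) & zone_ok)[0]:
        sites.append(
            BindingSite(
                template_id=template.id,
                start=int(pos),
                end=int(pos) + m,
                strand="-",
                n_mismatches=int(mism[pos]),
            )
        )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    pair: PrimerPair,
    template: SeqRecord,
    settings: InSilicoSettings = DEFAULT_SETTINGS,
) -> list[Amplicon]:
    """Predicted products of ``pair`` on ``template``.

    Every plus-strand forward site is paired with every minus-strand
    reverse site downstream of it within ``amp_max``; footprints may not
    overlap (product >= sum of primer lengths).  Sorted by position.
    """
    fwd_sites = [
        s
        for s in find_binding_sites(
            pair.forward, template, settings.max_mismatch, settings.three_prime_exact_nt
        )
        if s.strand == "+"
    ]
    if not fwd_sites:
        return []
    rev_sites = [
        s
        for s in find_binding_sites(
            pair.reverse, template, settings.max_mismatch, settings.three_prime_exact_nt
        )
        if s.strand == "-"
    ]
    amplicons = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start >= f.end and r.end - f.start <= settings.amp_max:
                amplicons.append(
                    Amplicon(
                        template_id=template.id,
                        start=f.start,
                        end=r.end,
                        forward_site=f,
                        reverse_site=r,
                    )
                )
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


Genome = Sequence[SeqRecord]


def predict_genome_amplicons(
    pair: PrimerPair, genome: Genome, settings: InSilicoSettings = DEFAULT_SETTINGS
) -> list[Amplicon]:
    out: list[Amplicon] = []
    for record in genome:
        out.extend(predict_amplicons(pair, record, settings))
    return out


def validate_marker(
    pair: PrimerPair,
    genomes: Sequence[tuple[str, Genome, str]],
    settings: InSilicoSettings = DEFAULT_SETTINGS,
) -> MarkerValidation:
    """Summarize amplification of ``pair`` across genomes.

    ``genomes`` is a sequence of ``(genome_id, records, expected_sex)``
    with ``expected_sex`` in {male, female, unknown}.
    """
    if not genomes:
        raise ValueError("validate_marker requires at least one genome")
    entries = []
    for genome_id, records, expected_sex in genomes:
        amps = predict_genome_amplicons(pair, records, settings)
        entries.append(
            GenomeAmplification(
                genome_id=genome_id,
                expected_sex=expected_sex,
                n_amplicons=len(amps),
                sizes=tuple(a.length_bp for a in amps),
            )
        )
    return MarkerValidation(
        primer_pair_id=pair.pair_id, target_type=pair.target_type, entries=tuple(entries)
    )


# ---------------------------------------------------------------------------
# Sex calling from a band pattern


@dataclass(frozen=True)
class SexCall:
    call: str  # male | female | failed
    bands: tuple[tuple[int, str], ...]  # (size, attributed pair_id)
    unattributed: tuple[int, ...] = ()

    @property
    def has_error_flag(self) -> bool:
        return bool(self.unattributed)


def call_sex(
    observed_sizes: Iterable[int],
    panel: MultiplexPanel,
    size_tolerance: float = 0.10,
) -> SexCall:
    """Interpret a multiplex gel lane.

    Each observed band is attributed to the panel member whose expected
    product size is within ``size_tolerance`` (relative); bands matching
    nothing are flagged.  No control band -> ``failed``; control plus at
    least one Y band -> ``male``; control alone -> ``female``.
    """
    attributed: list[tuple[int, str]] = []
    unattributed: list[int] = []
    present: set[str] = set()
    for size in observed_sizes:
        best_pair = None
        best_err = None
        for member in panel.members:
            err = abs(size - member.expected_amplicon_bp)
            if err <= size_tolerance * member.expected_amplicon_bp:
                if best_err is None or err < best_err:
                    best_err = err
                    best_pair = member
        if best_pair is None:
            unattributed.append(size)
        else:
            attributed.append((size, best_pair.pair_id))
            present.add(best_pair.pair_id)

    control_present = panel.control_pair.pair_id in present
    y_present = any(p.pair_id in present for p in panel.y_pairs)
    if not control_present:
        call = "failed"
    elif y_present:
        call = "male"
    else:
        call = "female"
    return SexCall(call=call, bands=tuple(attributed), unattributed=tuple(unattributed))


# ---------------------------------------------------------------------------
# Reports


def write_amplicon_report(
    rows: Iterable[tuple[str, str, Amplicon]], path: str | Path
) -> None:
    """TSV report; rows are (pair_id, genome_id, amplicon)."""
    with Path(path).open("w") as fh:
        fh.write(
            "pair_id\tgenome_id\ttemplate_id\tstart\tend\tlength_bp\t"
            "strand_f\tstrand_r\tmismatches_f\tmismatches_r\n"
        )
        for pair_id, genome_id, a in rows:
            fh.write(
                f"{pair_id}\t{genome_id}\t{a.template_id}\t{a.start}\t{a.end}\t"
                f"{a.length_bp}\t{a.forward_site.strand}\t{a.reverse_site.strand}\t"
                f"{a.forward_site.n_mismatches}\t{a.reverse_site.n_mismatches}\n"
            )


def read_genome_manifest(path: str | Path) -> list[tuple[str, str, str]]:
    """Rows of ``genome_id  fasta_path  expected_sex`` (paths relative to
    the manifest's directory are resolved against it)."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["genome_id", "fasta_path", "expected_sex"]:
            raise ValueError(f"{path}: bad manifest header {header}")
        for line in fh:
            if not line.strip():
                continue
            genome_id, fasta_path, sex = line.rstrip("\n").split("\t")
            if sex not in ("male", "female", "unknown"):
                raise ValueError(f"{path}: bad expected_sex {sex!r} for {genome_id}")
            fp = Path(fasta_path)
            if not fp.is_absolute():
                fp = path.parent / fp
            rows.append((genome_id, str(fp), sex))
    return rows
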