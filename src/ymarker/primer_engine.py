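"""Y-allele-anchored primer enumeration, thermodynamic scoring, dimer
screening, and multiplex panel assembly.

The design rule that makes a primer pair Y-specific is allele anchoring:
at least one primer of the pair places a fixed X-Y difference inside its
3'-terminal bases, so that on the X allele the polymerase faces a
3'-terminal mismatch and extension fails, while the amplified region as
a whole must span at least 2 fixed differences.  Pairs whose primers can
associate with each other (primer dimers) are rejected, and the final
multiplex panel combines two Y-specific pairs from distinct genes with
one autosomal control pair whose product sizes are separable on an
agarose gel.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from .divergence import FixedDiffSite
from .sequence_model import GeneRecord, normalize_sequence, reverse_complement

_PAIRS = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PrimerDesignError(ValueError):
    pass


class MultiplexInfeasibleError(RuntimeError):
    """No compatible (2 Y-specific + 1 control) triple exists; the
    message reports which constraint eliminated the most triples."""


# ---------------------------------------------------------------------------
# Elementary primer metrics


def gc_content(sequence: str) -> float:
    """Exact G+C fraction of a primer sequence (no N allowed)."""
    seq = normalize_sequence(sequence, context="gc_content input")
    if not seq:
        raise PrimerDesignError("gc_content of empty sequence is undefined")
    if "N" in seq:
        raise PrimerDesignError("gc_content requires an unambiguous sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(sequence: str, na_mM: float = 50.0, primer_uM: float = 0.25) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Uses the unified SantaLucia parameter set with the entropic salt
    correction 0.368 * (N-1) * ln[Na+]; deterministic for fixed inputs.
    """
    seq = normalize_sequence(sequence, context="melting_temp input")
    if not 15 <= len(seq) <= 30:
        raise PrimerDesignError(f"primer length {len(seq)} outside [15, 30]")
    if "N" in seq:
        raise PrimerDesignError("melting_temp requires an unambiguous sequence")
    return float(
        _mt.Tm_NN(
            Seq(seq),
            nn_table=_mt.DNA_NN3,
            Na=na_mM,
            dnac1=primer_uM * 1000.0,  # nM
            dnac2=0.0,
            saltcorr=5,
        )
    )


def wallace_tm(sequence: str) -> float:
    """Wallace rule 2(A+T) + 4(G+C); a rough secondary formula kept for
    cross-checking only."""
    seq = normalize_sequence(sequence, context="wallace_tm input")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


# ---------------------------------------------------------------------------
# Dimer scoring


def dimer_score(p1, p2) -> tuple[int, int]:
    """Longest complementary run between two primers in antiparallel
    orientation, over all ungapped offsets.

    Returns ``(max_comp_run, three_prime_run)`` where the second value is
    the longest run whose terminal base pair involves the 3' terminus of
    either primer.
    """
    s1 = p1.sequence if isinstance(p1, Primer) else normalize_sequence(p1)
    s2 = p2.sequence if isinstance(p2, Primer) else normalize_sequence(p2)
    t = s2[::-1]  # antiparallel: the 3' terminus of p2 sits at t[0]
    n1, n2 = len(s1), len(t)
    max_run = 0
    three_prime_run = 0
    for d in range(-(n2 - 1), n1):
        lo, hi = max(0, d), min(n1, n2 + d)
        run_start = None
        for i in range(lo, hi + 1):
            paired = i < hi and _PAIRS.get(s1[i]) == t[i - d]
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                length = i - run_start
                max_run = max(max_run, length)
                # run covers p1's 3' terminus (i == n1-1) or p2's (j == 0)
                if i - 1 == n1 - 1 or run_start == d:
                    three_prime_run = max(three_prime_run, length)
                run_start = None
    return max_run, three_prime_run


def dimer_reject(
    s1: str, s2: str, max_comp_run: int = 8, max_three_prime_run: int = 4
) -> bool:
    """Fast substring-based equivalent of thresholding :func:`dimer_score`.

    A complementary run of length >= k exists iff the reverse complement
    of some k-mer of one primer occurs in the other; a 3'-terminal run of
    length >= k exists iff the reverse complement of a primer's last k
    bases occurs in its partner.
    """
    k = max_comp_run
    if len(s1) >= k:
        for i in range(len(s1) - k + 1):
            if reverse_complement(s1[i : i + k]) in s2:
                return True
    j = max_three_prime_run
    if len(s1) >= j and reverse_complement(s1[-j:]) in s2:
        return True
    if len(s2) >= j and reverse_complement(s2[-j:]) in s1:
        return True
    return False


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Primer:
    """A single oligo written 5'->3'.

    ``anchor_sites`` lists the fixed X-Y differences the primer covers as
    ``(site, offset_from_3prime_end)`` pairs; offset 0 is the terminal base.
    """

    sequence: str
    gene_id: str
    orientation: str  # "forward" | "reverse"
    tm_c: float
    gc_fraction: float
    anchor_sites: tuple = ()

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        expected_gc = (self.sequence.count("G") + self.sequence.count("C")) / len(
            self.sequence
        )
        if abs(self.gc_fraction - expected_gc) > 1e-9:
            raise ValueError("gc_fraction does not match sequence")
        for _, offset in self.anchor_sites:
            if offset >= len(self.sequence):
                raise ValueError("anchor offset beyond primer length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair with its expected product.

    ``forward_start`` / ``reverse_end`` are 0-based half-open coordinates
    of the amplicon on the design template.
    """

    pair_id: str
    forward: Primer
    reverse: Primer
    expected_amplicon_bp: int
    target_type: str  # "y_specific" | "autosomal_control"
    n_fixed_diffs_covered: int = 0
    forward_start: int = 0
    reverse_end: int = 0

    def __post_init__(self) -> None:
        if self.target_type not in ("y_specific", "autosomal_control"):
            raise ValueError(f"bad target_type {self.target_type!r}")
        if self.target_type == "y_specific" and self.n_fixed_diffs_covered < 2:
            raise ValueError("y_specific pair must cover >= 2 fixed differences")
        if self.expected_amplicon_bp < len(self.forward) + len(self.reverse):
            raise ValueError("amplicon shorter than the two primer footprints")

    @property
    def gene_id(self) -> str:
        return self.forward.gene_id


@dataclass(frozen=True)
class MultiplexPanel:
    """Two Y-specific pairs from distinct genes plus one autosomal control,
    with gel-resolvable product sizes."""

    y_pairs: tuple[PrimerPair, PrimerPair]
    control_pair: PrimerPair
    min_size_gap_bp: int

    def __post_init__(self) -> None:
        if any(p.target_type != "y_specific" for p in self.y_pairs):
            raise ValueError("y_pairs must be y_specific")
        if self.control_pair.target_type != "autosomal_control":
            raise ValueError("control_pair must be autosomal_control")
        if self.y_pairs[0].gene_id == self.y_pairs[1].gene_id:
            raise ValueError("the two Y-specific pairs must target distinct genes")
        sizes = sorted(self.amplicon_sizes)
        for a, b in zip(sizes, sizes[1:]):
            if b - a < self.min_size_gap_bp:
                raise ValueError(
                    f"amplicon sizes {sizes} violate min gap {self.min_size_gap_bp}"
                )

    @property
    def members(self) -> tuple[PrimerPair, PrimerPair, PrimerPair]:
        return (*self.y_pairs, self.control_pair)

    @property
    def amplicon_sizes(self) -> list[int]:
        return [p.expected_amplicon_bp for p in self.members]


@dataclass(frozen=True)
class PrimerConstraints:
    """Window filters for candidate enumeration.

    Thermodynamic windows are chosen so the panel works at a 58 degC
    annealing step; the anchor window equals the 3'-exact zone of the
    in silico binding model so that an anchored primer is guaranteed to
    reject the X allele.
    """

    len_min: int = 18
    len_max: int = 24
    tm_min: float = 55.0
    tm_max: float = 62.0
    gc_min: float = 0.30
    gc_max: float = 0.70
    amp_min: int = 100
    amp_max: int = 600
    na_mM: float = 50.0
    primer_uM: float = 0.25
    anchor_3prime_nt: int = 3
    min_amplicon_fixed_diffs: int = 2
    max_comp_run: int = 8
    max_three_prime_run: int = 4


DEFAULT_CONSTRAINTS = PrimerConstraints()


def passes_qc(sequence: str, constraints: PrimerConstraints = DEFAULT_CONSTRAINTS) -> bool:
    """Length / GC / self-dimer QC used for both designed and imported primers."""
    if not constraints.len_min <= len(sequence) <= constraints.len_max:
        return False
    if not constraints.gc_min <= gc_content(sequence) <= constraints.gc_max:
        return False
    _, three_prime = dimer_score(sequence, sequence)
    return three_prime < constraints.max_three_prime_run


# ---------------------------------------------------------------------------
# Candidate enumeration


@dataclass(frozen=True)
class _Window:
    start: int
    end: int  # half-open on the design template
    sequence: str  # primer 5'->3'
    tm_c: float
    gc: float
    anchors: tuple  # (site, offset_from_3prime)


def _qc_windows(
    template: str,
    fixed_by_pos: dict[int, FixedDiffSite],
    constraints: PrimerConstraints,
    orientation: str,
) -> list[_Window]:
    out = []
    n = len(template)
    for length in range(constraints.len_min, constraints.len_max + 1):
        for start in range(0, n - length + 1):
            end = start + length
            window = template[start:end]
            if "N" in window:
                continue
            gc = (window.count("G") + window.count("C")) / length
            if not constraints.gc_min <= gc <= constraints.gc_max:
                continue
            seq = window if orientation == "forward" else reverse_complement(window)
            tm = melting_temp(seq, constraints.na_mM, constraints.primer_uM)
            if not constraints.tm_min <= tm <= constraints.tm_max:
                continue
            if dimer_reject(
                seq, seq, constraints.max_comp_run, constraints.max_three_prime_run
            ):
                continue
            anchors = []
            for pos in range(start, end):
                site = fixed_by_pos.get(pos)
                if site is not None:
                    offset = (end - 1 - pos) if orientation == "forward" else (pos - start)
                    anchors.append((site, offset))
            out.append(
                _Window(start=start, end=end, sequence=seq, tm_c=tm, gc=gc, anchors=tuple(anchors))
            )
    return out


def _is_anchored(w: _Window, k: int) -> bool:
    return any(offset < k for _, offset in w.anchors)


def enumerate_candidates(
    gene: GeneRecord,
    fixed_sites: Sequence[FixedDiffSite],
    constraints: PrimerConstraints = DEFAULT_CONSTRAINTS,
    target_type: str = "y_specific",
    template: str | None = None,
    max_pairs: int | None = None,
) -> list[PrimerPair]:
    """Enumerate all primer pairs on the Y (or autosomal) template that
    satisfy the window, product-size, Y-anchoring, and dimer filters.

    For ``y_specific`` pairs the amplicon must cover at least
    ``min_amplicon_fixed_diffs`` fixed X-Y differences and at least one
    primer must carry a fixed difference within its 3'-terminal
    ``anchor_3prime_nt`` bases.  ``fixed_sites`` must be expressed in the
    coordinate frame of the template (``gene.y_sequence`` by default).
    Output is sorted by (gene_id, forward start, reverse end, lengths).
    ``max_pairs`` truncates the enumeration deterministically (leftmost
    forward windows first) once that many pairs have been collected.
    """
    tpl = normalize_sequence(template if template is not None else gene.y_sequence)
    fixed_by_pos = {s.column_index: s for s in fixed_sites if s.column_index < len(tpl)}
    site_positions = sorted(fixed_by_pos)

    fwd = _qc_windows(tpl, fixed_by_pos, constraints, "forward")
    rev = _qc_windows(tpl, fixed_by_pos, constraints, "reverse")
    rev.sort(key=lambda w: w.end)
    rev_ends = [w.end for w in rev]

    k = constraints.anchor_3prime_nt
    if target_type == "y_specific":
        fwd_a = [w for w in fwd if _is_anchored(w, k)]
        rev_a = [w for w in rev if _is_anchored(w, k)]
        rev_a.sort(key=lambda w: w.end)
        rev_a_ends = [w.end for w in rev_a]
        # (anchored fwd x all rev) + (all fwd x anchored rev)
        combos = [(fwd_a, rev, rev_ends), (fwd, rev_a, rev_a_ends)]
    else:
        combos = [(fwd, rev, rev_ends)]

    seen: set[tuple[int, int, int, int]] = set()
    pairs: list[PrimerPair] = []

    def candidate_stream(fwd_list, rev_list, ends):
        """(f, r) windows in-range for the amplicon size limits.

        Without a cap, plain nested order.  With ``max_pairs`` and a
        large search space, a strided grid over (forward window, reverse
        window) is enumerated instead, so the truncated candidate set
        stays spread over both primer positions and product sizes rather
        than piling up in one corner of the template.
        """
        fwd_sorted = sorted(fwd_list, key=lambda w: (w.start, w.end))
        ranges = []
        for f in fwd_sorted:
            lo = bisect_left(ends, f.start + max(constraints.amp_min, 1))
            hi = bisect_right(ends, f.start + constraints.amp_max)
            ranges.append((f, lo, hi))
        total = sum(hi - lo for _, lo, hi in ranges)
        stride = 1
        if max_pairs is not None and total > 3 * max_pairs:
            stride = max(1, math.isqrt(total // (3 * max_pairs)))
        for f, lo, hi in ranges[::stride]:
            for r in rev_list[lo:hi:stride]:
                yield f, r

    for fwd_list, rev_list, ends in combos:
        if max_pairs is not None and len(pairs) >= max_pairs:
            break
        for f, r in candidate_stream(fwd_list, rev_list, ends):
            if max_pairs is not None and len(pairs) >= max_pairs:
                break
            if r.start < f.end:
                continue  # overlapping footprints
            key = (f.start, f.end, r.start, r.end)
            if key in seen:
                continue
            amplicon = r.end - f.start
            if not constraints.amp_min <= amplicon <= constraints.amp_max:
                continue
            if target_type == "y_specific":
                n_covered = (
                    bisect_right(site_positions, r.end - 1)
                    - bisect_left(site_positions, f.start)
                )
                if n_covered < constraints.min_amplicon_fixed_diffs:
                    continue
                if not (_is_anchored(f, k) or _is_anchored(r, k)):
                    continue
            else:
                n_covered = 0
            if dimer_reject(
                f.sequence,
                r.sequence,
                constraints.max_comp_run,
                constraints.max_three_prime_run,
            ):
                continue
            seen.add(key)
            forward = Primer(
                sequence=f.sequence,
                gene_id=gene.gene_id,
                orientation="forward",
                tm_c=f.tm_c,
                gc_fraction=f.gc,
                anchor_sites=f.anchors,
            )
            reverse = Primer(
                sequence=r.sequence,
                gene_id=gene.gene_id,
                orientation="reverse",
                tm_c=r.tm_c,
                gc_fraction=r.gc,
                anchor_sites=r.anchors,
            )
            pairs.append(
                PrimerPair(
                    pair_id=f"{gene.gene_id}:{f.start}-{r.end}",
                    forward=forward,
                    reverse=reverse,
                    expected_amplicon_bp=amplicon,
                    target_type=target_type,
                    n_fixed_diffs_covered=n_covered,
                    forward_start=f.start,
                    reverse_end=r.end,
                )
            )
    pairs.sort(
        key=lambda p: (
            p.gene_id,
            p.forward_start,
            p.reverse_end,
            len(p.forward),
            len(p.reverse),
        )
    )
    return pairs


# ---------------------------------------------------------------------------
# Multiplex assembly


@lru_cache(maxsize=200_000)
def _dimer_score_cached(s1: str, s2: str) -> tuple[int, int]:
    return dimer_score(s1, s2)


def _cross_dimer_stats(a: PrimerPair, b: PrimerPair) -> tuple[int, int, int]:
    """(worst max_comp_run, worst three_prime_run, summed score) across the
    four inter-pair primer combinations."""
    worst_run = worst_3p = total = 0
    for p in (a.forward, a.reverse):
        for q in (b.forward, b.reverse):
            run, three = _dimer_score_cached(p.sequence, q.sequence)
            worst_run = max(worst_run, run)
            worst_3p = max(worst_3p, three)
            total += run + three
    return worst_run, worst_3p, total


def _diverse_cap(
    pairs: list[PrimerPair], limit: int, pre_rank, size_band: int
) -> list[PrimerPair]:
    """Keep at most ``limit`` pairs spread over amplicon-size bands.

    Top-ranked candidates of one gene are near-duplicates with almost
    identical product sizes and shared primers; a round-robin over size
    bands (width = the multiplex gap) keeps the capped set both
    gel-separable and uncorrelated in its dimer failures.
    """
    bands: dict[int, list[PrimerPair]] = {}
    for p in sorted(pairs, key=pre_rank):
        bands.setdefault(p.expected_amplicon_bp // size_band, []).append(p)
    kept: list[PrimerPair] = []
    queues = [bands[k] for k in sorted(bands)]
    while len(kept) < limit and any(queues):
        for q in queues:
            if q:
                kept.append(q.pop(0))
                if len(kept) >= limit:
                    break
    return kept


def select_multiplex(
    y_candidates: Sequence[PrimerPair],
    control_candidates: Sequence[PrimerPair],
    min_size_gap_bp: int = 60,
    max_comp_run: int = 8,
    max_three_prime_run: int = 4,
    _cap: int = 200_000,
) -> MultiplexPanel:
    """Pick the best feasible (2 Y-specific + 1 control) triple.

    Feasibility: the two Y pairs come from distinct genes, all pairwise
    amplicon-size gaps are >= ``min_size_gap_bp`` and no inter-pair primer
    combination violates the dimer limits.  Triples are ranked by total
    fixed differences covered (desc), then total inter-pair dimer score
    (asc), then gene ids.  Raises :class:`MultiplexInfeasibleError` naming
    the constraint that eliminated the most triples when nothing fits.
    """
    if not y_candidates or not control_candidates:
        raise MultiplexInfeasibleError(
            "empty candidate list: "
            + ("no y_specific candidates; " if not y_candidates else "")
            + ("no control candidates" if not control_candidates else "")
        )
    y_list = [p for p in y_candidates if p.target_type == "y_specific"]
    c_list = [p for p in control_candidates if p.target_type == "autosomal_control"]

    def pre_rank(p: PrimerPair) -> tuple:
        return (-p.n_fixed_diffs_covered, p.gene_id, p.forward_start, p.reverse_end)

    n_triples = len(y_list) * (len(y_list) - 1) // 2 * len(c_list)
    if n_triples > _cap:
        band = max(min_size_gap_bp, 1)
        by_gene: dict[str, list[PrimerPair]] = {}
        for p in y_list:
            by_gene.setdefault(p.gene_id, []).append(p)
        y_list = [
            p for ps in by_gene.values() for p in _diverse_cap(ps, 20, pre_rank, band)
        ]
        c_list = _diverse_cap(c_list, 20, pre_rank, band)

    genes = sorted({p.gene_id for p in y_list})
    if len(genes) < 2:
        raise MultiplexInfeasibleError(
            f"y_specific candidates span only {len(genes)} gene(s); 2 distinct genes required"
        )

    failures = {"size_gap": 0, "dimer": 0}
    best = None
    best_key = None
    y_sorted = sorted(y_list, key=pre_rank)
    for i, y1 in enumerate(y_sorted):
        for y2 in y_sorted[i + 1 :]:
            if y1.gene_id == y2.gene_id:
                continue
            for ctrl in c_list:
                sizes = sorted(
                    (y1.expected_amplicon_bp, y2.expected_amplicon_bp, ctrl.expected_amplicon_bp)
                )
                if any(b - a < min_size_gap_bp for a, b in zip(sizes, sizes[1:])):
                    failures["size_gap"] += 1
                    continue
                total_dimer = 0
                ok = True
                for a, b in ((y1, y2), (y1, ctrl), (y2, ctrl)):
                    run, three, score = _cross_dimer_stats(a, b)
                    if run >= max_comp_run or three >= max_three_prime_run:
                        ok = False
                        break
                    total_dimer += score
                if not ok:
                    failures["dimer"] += 1
                    continue
                coverage = y1.n_fixed_diffs_covered + y2.n_fixed_diffs_covered
                key = (
                    -coverage,
                    total_dimer,
                    tuple(sorted((y1.gene_id, y2.gene_id))),
                    ctrl.gene_id,
                    y1.pair_id,
                    y2.pair_id,
                    ctrl.pair_id,
                )
                if best_key is None or key < best_key:
                    best_key = key
                    ya, yb = sorted((y1, y2), key=lambda p: (p.gene_id, p.pair_id))
                    best = MultiplexPanel(
                        y_pairs=(ya, yb), control_pair=ctrl, min_size_gap_bp=min_size_gap_bp
                    )
    if best is None:
        binding = max(failures, key=failures.get)
        raise MultiplexInfeasibleError(
            f"no feasible multiplex triple; binding constraint: {binding} "
            f"(size_gap rejected {failures['size_gap']}, dimer rejected {failures['dimer']})"
        )
    return best


# ---------------------------------------------------------------------------
# Primer table I/O and the published three-primer panel


_TABLE_COLUMNS = [
    "primer_id",
    "type",
    "gene_id",
    "forward_seq",
    "reverse_seq",
    "xy_ds",
    "amplicon_bp",
]


@dataclass(frozen=True)
class PrimerTableRow:
    primer_id: str
    type: str  # "XY" | "autosomal"
    gene_id: str
    forward_seq: str
    reverse_seq: str
    xy_ds: float | None
    amplicon_bp: int


def read_primer_table(path: str | Path) -> list[PrimerTableRow]:
    rows = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TABLE_COLUMNS:
            raise ValueError(f"{path}: expected columns {_TABLE_COLUMNS}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, ptype, gene, fwd, rev, ds, amp = line.rstrip("\n").split("\t")
            rows.append(
                PrimerTableRow(
                    primer_id=pid,
                    type=ptype,
                    gene_id=gene,
                    forward_seq=normalize_sequence(fwd),
                    reverse_seq=normalize_sequence(rev),
                    xy_ds=None if ds == "NA" else float(ds),
                    amplicon_bp=int(amp),
                )
            )
    return rows


def write_primer_table(rows: Iterable[PrimerTableRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in rows:
            ds = "NA" if r.xy_ds is None else f"{r.xy_ds:g}"
            fh.write(
                f"{r.primer_id}\t{r.type}\t{r.gene_id}\t{r.forward_seq}\t"
                f"{r.reverse_seq}\t{ds}\t{r.amplicon_bp}\n"
            )


def load_published_primers() -> list[PrimerTableRow]:
    """The packaged three-primer sexing panel (2 Y-linked + 1 autosomal)."""
    from importlib.resources import files

    return read_primer_table(files("ymarker.data") / "table1_primers.tsv")
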