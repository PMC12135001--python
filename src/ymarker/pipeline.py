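"""End-to-end orchestration: dS estimation, gene selection, fixed-site
calling, primer/panel design, and in silico validation on a cohort.

This is the library layer behind the command-line interface; each stage
is usable on its own and everything is deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import divergence as dv
from . import insilico_pcr as ip
from . import primer_engine as pe
from .sequence_model import GeneRecord, SeqRecord, align_global
from .synthetic_data import SyntheticCohort, autosomal_marker

log = logging.getLogger("ymarker")


def estimate_gene_ds(gene: GeneRecord) -> float:
    """X-Y synonymous divergence of a gene: mean NG86 dS between the Y
    copy and each X haplotype (codon-aligned; sequences of unequal
    length are globally aligned first).  Returns ``nan`` if every
    comparison is saturated.
    """
    if not gene.x_sequences:
        raise ValueError(f"gene {gene.gene_id} has no X haplotypes")
    values = []
    for x in gene.x_sequences:
        if len(x.sequence) == len(gene.y_sequence):
            a, b = gene.y_sequence, x.sequence
        else:
            aln = align_global(gene.y_sequence, x.sequence)
            a, b = aln.seq_a_aligned, aln.seq_b_aligned
        est = dv.nei_gojobori_ds(a, b)
        if not est.ds_saturated:
            values.append(est.ds)
    return sum(values) / len(values) if values else math.nan


@dataclass
class DesignResult:
    """Everything the design stage produced: the per-gene report rows,
    candidate lists, and the selected multiplex panel (``None`` when
    panel assembly was not requested)."""

    panel: pe.MultiplexPanel | None
    selected_genes: list[GeneRecord]
    fixed_sites: dict[str, list[dv.FixedDiffSite]]  # CDS coordinates, per gene
    y_candidates: dict[str, list[pe.PrimerPair]]
    control_candidates: list[pe.PrimerPair]
    gene_report: list[dict]


def design_panel(
    cohort: SyntheticCohort,
    constraints: pe.PrimerConstraints = pe.DEFAULT_CONSTRAINTS,
    top_k: int = 20,
    min_intron_bp: int = 300,
    min_size_gap_bp: int = 60,
    max_candidates_per_gene: int = 400,
    max_control_candidates: int = 150,
    assemble_panel: bool = True,
) -> DesignResult:
    """Run the full marker-design stage on a cohort.

    Per gene: estimate dS from the Y and X coding copies; select
    candidate genes (Y-expressed, oldest stratum, top-k dS, intron long
    enough); call fixed X-Y differences on the coding alignment; lift
    them through the exon/intron structure onto the genomic marker
    sequence; enumerate anchored primer pairs there.  Control pairs are
    enumerated on autosomal markers, and the best gel-compatible
    (2 Y + 1 control) triple is assembled.
    """
    genes = []
    for g in cohort.gene_records:
        g.ds = estimate_gene_ds(g)
        genes.append(g)

    selected = dv.select_candidate_genes(genes, top_k=top_k, min_intron_bp=min_intron_bp)
    log.info("selected %d of %d sex-linked genes", len(selected), len(genes))

    fixed_sites: dict[str, list[dv.FixedDiffSite]] = {}
    y_candidates: dict[str, list[pe.PrimerPair]] = {}
    report: list[dict] = []
    selected_ids = {g.gene_id for g in selected}
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "ds": g.ds,
            "n_fixed_diffs": "",
            "selected": g.gene_id in selected_ids,
            "reason": "",
        }
        if g.gene_id not in selected_ids:
            if not g.y_expressed:
                row["reason"] = "y_not_expressed"
            elif g.stratum != min(x.stratum for x in genes):
                row["reason"] = "younger_stratum"
            elif g.intron_length_bp < min_intron_bp:
                row["reason"] = "short_intron"
            else:
                row["reason"] = "below_top_k_ds"
            report.append(row)
            continue
        y_rec = SeqRecord(id=f"{g.gene_id}|Y", sequence=g.y_sequence)
        sites = dv.call_fixed_differences(y_rec, g.x_sequences, gene_id=g.gene_id)
        fixed_sites[g.gene_id] = sites
        row["n_fixed_diffs"] = len(sites)
        structure = cohort.structures[g.gene_id]
        lifted = structure.lift_sites(sites)
        cands = pe.enumerate_candidates(
            g,
            lifted,
            constraints,
            target_type="y_specific",
            template=cohort.y_markers[g.gene_id],
            max_pairs=max_candidates_per_gene,
        )
        y_candidates[g.gene_id] = cands
        if not cands:
            row["reason"] = "no_anchored_primer_pair"
        report.append(row)
        log.info(
            "gene %s: dS=%.3f, %d fixed differences, %d candidate pairs",
            g.gene_id,
            g.ds,
            len(sites),
            len(cands),
        )

    control_candidates: list[pe.PrimerPair] = []
    for g in cohort.autosomal_genes:
        control_candidates.extend(
            pe.enumerate_candidates(
                g,
                [],
                constraints,
                target_type="autosomal_control",
                template=autosomal_marker(cohort, g.gene_id),
                max_pairs=max_control_candidates,
            )
        )

    all_y = [p for cands in y_candidates.values() for p in cands]
    if not assemble_panel:
        return DesignResult(
            panel=None,
            selected_genes=selected,
            fixed_sites=fixed_sites,
            y_candidates=y_candidates,
            control_candidates=control_candidates,
            gene_report=report,
        )
    panel = pe.select_multiplex(
        all_y,
        control_candidates,
        min_size_gap_bp=min_size_gap_bp,
        max_comp_run=constraints.max_comp_run,
        max_three_prime_run=constraints.max_three_prime_run,
    )
    log.info(
        "panel: %s + %s (Y) with control %s, product sizes %s",
        panel.y_pairs[0].pair_id,
        panel.y_pairs[1].pair_id,
        panel.control_pair.pair_id,
        panel.amplicon_sizes,
    )
    return DesignResult(
        panel=panel,
        selected_genes=selected,
        fixed_sites=fixed_sites,
        y_candidates=y_candidates,
        control_candidates=control_candidates,
        gene_report=report,
    )


def write_gene_report(report: list[dict], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tds\tn_fixed_diffs\tselected\treason\n")
        for r in report:
            ds = "NA" if r["ds"] is None or (isinstance(r["ds"], float) and math.isnan(r["ds"])) else f"{r['ds']:.4f}"
            fh.write(
                f"{r['gene_id']}\t{ds}\t{r['n_fixed_diffs']}\t"
                f"{'true' if r['selected'] else 'false'}\t{r['reason']}\n"
            )


def validate_panel(
    panel: pe.MultiplexPanel,
    genomes: Sequence[tuple[str, Sequence[SeqRecord], str]],
    settings: ip.InSilicoSettings = ip.DEFAULT_SETTINGS,
) -> tuple[list[ip.MarkerValidation], list[tuple[str, str, ip.Amplicon]]]:
    """Validate every panel member against every genome.

    Returns the per-pair validations and a flat amplicon report.
    Amplicon prediction is cached per unique template record, so genomes
    sharing chromosome templates are only scanned once.
    """
    cache: dict[tuple[str, str], list[ip.Amplicon]] = {}

    def amps(pair: pe.PrimerPair, record: SeqRecord) -> list[ip.Amplicon]:
        key = (pair.pair_id, record.id)
        if key not in cache:
            cache[key] = ip.predict_amplicons(pair, record, settings)
        return cache[key]

    validations = []
    report_rows: list[tuple[str, str, ip.Amplicon]] = []
    for pair in panel.members:
        entries = []
        for genome_id, records, expected_sex in genomes:
            found = [a for r in records for a in amps(pair, r)]
            for a in found:
                report_rows.append((pair.pair_id, genome_id, a))
            entries.append(
                ip.GenomeAmplification(
                    genome_id=genome_id,
                    expected_sex=expected_sex,
                    n_amplicons=len(found),
                    sizes=tuple(a.length_bp for a in found),
                )
            )
        validations.append(
            ip.MarkerValidation(
                primer_pair_id=pair.pair_id,
                target_type=pair.target_type,
                entries=tuple(entries),
            )
        )
    return validations, report_rows


def write_marker_validation(
    validations: Sequence[ip.MarkerValidation], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("pair_id\ttarget_type\tgenome_id\texpected_sex\tn_amplicons\tsizes\tvalid\n")
        for v in validations:
            for e in v.entries:
                sizes = ",".join(str(s) for s in e.sizes)
                fh.write(
                    f"{v.primer_pair_id}\t{v.target_type}\t{e.genome_id}\t"
                    f"{e.expected_sex}\t{e.n_amplicons}\t{sizes}\t"
                    f"{'true' if v.valid else 'false'}\n"
                )


# ---------------------------------------------------------------------------
# Panel serialization


def save_panel(panel: pe.MultiplexPanel, path: str | Path) -> None:
    def pair_dict(p: pe.PrimerPair) -> dict:
        return {
            "pair_id": p.pair_id,
            "gene_id": p.gene_id,
            "target_type": p.target_type,
            "forward_seq": p.forward.sequence,
            "reverse_seq": p.reverse.sequence,
            "expected_amplicon_bp": p.expected_amplicon_bp,
            "n_fixed_diffs_covered": p.n_fixed_diffs_covered,
            "forward_start": p.forward_start,
            "reverse_end": p.reverse_end,
        }

    data = {
        "min_size_gap_bp": panel.min_size_gap_bp,
        "y_pairs": [pair_dict(p) for p in panel.y_pairs],
        "control_pair": pair_dict(panel.control_pair),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_panel(
    path: str | Path, constraints: pe.PrimerConstraints = pe.DEFAULT_CONSTRAINTS
) -> pe.MultiplexPanel:
    data = yaml.safe_load(Path(path).read_text())

    def build_pair(d: dict) -> pe.PrimerPair:
        def build_primer(seq: str, orientation: str) -> pe.Primer:
            return pe.Primer(
                sequence=seq,
                gene_id=d["gene_id"],
                orientation=orientation,
                tm_c=pe.melting_temp(seq, constraints.na_mM, constraints.primer_uM),
                gc_fraction=pe.gc_content(seq),
            )

        return pe.PrimerPair(
            pair_id=d["pair_id"],
            forward=build_primer(d["forward_seq"], "forward"),
            reverse=build_primer(d["reverse_seq"], "reverse"),
            expected_amplicon_bp=d["expected_amplicon_bp"],
            target_type=d["target_type"],
            n_fixed_diffs_covered=d["n_fixed_diffs_covered"],
            forward_start=d["forward_start"],
            reverse_end=d["reverse_end"],
        )

    return pe.MultiplexPanel(
        y_pairs=tuple(build_pair(d) for d in data["y_pairs"]),
        control_pair=build_pair(data["control_pair"]),
        min_size_gap_bp=data["min_size_gap_bp"],
    )


def panel_to_table_rows(
    panel: pe.MultiplexPanel, ds_by_gene: dict[str, float] | None = None
) -> list[pe.PrimerTableRow]:
    rows = []
    for p in panel.members:
        is_y = p.target_type == "y_specific"
        ds = (ds_by_gene or {}).get(p.gene_id)
        rows.append(
            pe.PrimerTableRow(
                primer_id=p.pair_id,
                type="XY" if is_y else "autosomal",
                gene_id=p.gene_id,
                forward_seq=p.forward.sequence,
                reverse_seq=p.reverse.sequence,
                xy_ds=ds if is_y else None,
                amplicon_bp=p.expected_amplicon_bp,
            )
        )
    return rows
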