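"""Simulation of XY gene systems, cultivar cohorts, and genome templates.

The generator emulates the data regime the marker-design pipeline
assumes: sex-linked gene pairs whose X-Y synonymous divergence is
controlled per evolutionary stratum (the oldest stratum in the real
system reaches dS ~ 0.4; the marker genes sit near 0.2), several X
haplotypes from distinct cultivars with intra-X diversity far below the
X-Y divergence, intron-bearing gene structures, and assembled male
(X + Y) and female (X + X) genome templates, plus autosomal control
genes shared by both sexes.

All randomness flows from one integer seed through a hierarchical
``numpy`` ``SeedSequence``, so any sub-object can be regenerated
byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .divergence import (
    FixedDiffSite,
    _CODON_TO_AA,
    _STOP_CODONS,
    nei_gojobori_ds,
)
from .insilico_pcr import (
    DEFAULT_SETTINGS,
    InSilicoSettings,
    call_sex,
    predict_amplicons,
)
from .primer_engine import MultiplexPanel
from .sequence_model import GeneRecord, SeqRecord

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOP_CODONS
]

_NONSYN_ACCEPT = 0.2  # purifying-selection acceptance for nonsynonymous hits


def _aa(codon: str) -> str | None:
    return _CODON_TO_AA.get(codon)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the validated assay's regime: 12 cultivars with 16
    samples each (192 total, half male), 3 X haplotype sources, 300-codon
    genes with a >= 300 bp intron, an old stratum near dS 0.20 (the
    marker genes' range) plus a younger one, a 61% Y-expression rate
    among sex-linked genes, and a phenotyping error rate of 1/192
    matching the single discordant sample.
    """

    n_genes: int = 12
    strata: tuple[tuple[int, float], ...] = ((0, 0.20), (1, 0.05))
    n_x_haplotypes: int = 3
    intra_x_diversity: float = 0.002
    gene_length_codons: int = 300
    intron_length_bp: int = 400
    n_autosomal_genes: int = 2
    n_cultivars: int = 12
    n_samples_per_cultivar: int = 16
    phenotyping_error_rate: float = 1.0 / 192.0
    y_expressed_fraction: float = 347.0 / 565.0
    spacer_range_bp: tuple[int, int] = (200, 1000)
    seed: int = 0

    def validate(self) -> None:
        checks = {
            "n_genes": self.n_genes >= 0,
            "strata": len(self.strata) > 0
            and all(0.0 <= ds <= 0.74 for _, ds in self.strata),
            "n_x_haplotypes": self.n_x_haplotypes >= 1,
            "intra_x_diversity": 0.0 <= self.intra_x_diversity < 1.0,
            "gene_length_codons": self.gene_length_codons >= 10,
            "intron_length_bp": self.intron_length_bp >= 0,
            "n_autosomal_genes": self.n_autosomal_genes >= 1,
            "n_cultivars": self.n_cultivars >= 1,
            "n_samples_per_cultivar": self.n_samples_per_cultivar >= 1,
            "phenotyping_error_rate": 0.0 <= self.phenotyping_error_rate <= 1.0,
            "y_expressed_fraction": 0.0 <= self.y_expressed_fraction <= 1.0,
            "spacer_range_bp": 0 < self.spacer_range_bp[0] <= self.spacer_range_bp[1],
        }
        for name, ok in checks.items():
            if not ok:
                raise SimulationError(f"invalid config field: {name}")
        min_ds = min(ds for _, ds in self.strata)
        if min_ds > 0 and self.intra_x_diversity > min_ds / 5.0:
            raise SimulationError(
                "invalid config field: intra_x_diversity (must be well below "
                "the smallest stratum target_ds)"
            )


@dataclass(frozen=True)
class GeneStructure:
    """Exon/intron layout of one simulated gene on its marker sequence.

    The intron is inserted at CDS offset ``intron_at_bp`` (a codon
    boundary); a CDS coordinate ``p`` maps to marker coordinate ``p`` if
    ``p < intron_at_bp`` else ``p + intron_length_bp``.
    """

    gene_id: str
    intron_at_bp: int
    intron_length_bp: int

    def cds_to_marker(self, pos: int) -> int:
        return pos if pos < self.intron_at_bp else pos + self.intron_length_bp

    def lift_sites(self, sites: list[FixedDiffSite]) -> list[FixedDiffSite]:
        return [
            replace(s, column_index=self.cds_to_marker(s.column_index)) for s in sites
        ]


@dataclass
class SampleGenome:
    sample_id: str
    cultivar: str
    genotypic_sex: str  # male | female
    records: tuple[SeqRecord, ...]


@dataclass
class SyntheticCohort:
    """A simulated cohort with full ground truth."""

    config: SimulationConfig
    gene_records: list[GeneRecord]
    structures: dict[str, GeneStructure]
    y_markers: dict[str, str]  # gene_id -> genomic Y marker sequence
    true_fixed_sites: dict[str, list[FixedDiffSite]]  # CDS coordinates
    autosomal_genes: list[GeneRecord]
    x_templates: list[SeqRecord]  # one chromosome-like record per X haplotype
    y_template: SeqRecord
    autosome_template: SeqRecord
    samples: list[SampleGenome]

    @property
    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "cultivar": s.cultivar,
                    "genotypic_sex": s.genotypic_sex,
                }
                for s in self.samples
            ]
        )

    def genomes(self) -> list[tuple[str, tuple[SeqRecord, ...], str]]:
        return [(s.sample_id, s.records, s.genotypic_sex) for s in self.samples]


# ---------------------------------------------------------------------------
# Mutation of coding sequence to a target dS


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n_codons))


def mutate_cds(cds: str, target_ds: float, seed: int | np.random.Generator) -> str:
    """Mutate a coding sequence until its NG86 dS against the input first
    reaches ``target_ds``.

    Substitutions are proposed uniformly; synonymous changes are always
    accepted, nonsynonymous ones with a reduced probability (purifying
    selection), and stop codons are never created.  Deterministic for a
    fixed seed.
    """
    if len(cds) % 3 != 0:
        raise SimulationError("cds length must be a multiple of 3")
    if target_ds < 0 or target_ds >= 0.74:
        raise SimulationError("target_ds must be in [0, 0.74)")
    if target_ds == 0:
        return cds
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cds)
    max_proposals = 5000 * max(1, math.ceil(target_ds * n))
    current = list(cds)
    for _ in range(max_proposals):
        pos = int(rng.integers(n))
        old = current[pos]
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        ci = pos // 3
        codon = current[3 * ci] + current[3 * ci + 1] + current[3 * ci + 2]
        mutant = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if mutant in _STOP_CODONS:
            continue
        synonymous = _aa(codon) == _aa(mutant)
        if not synonymous and rng.random() > _NONSYN_ACCEPT:
            continue
        current[pos] = new
        # nonsynonymous hits also shift the estimate (site counts and
        # pathway averaging), so re-estimate after every accepted change
        est = nei_gojobori_ds("".join(current), cds)
        if not est.ds_saturated and est.ds >= target_ds:
            return "".join(current)
    raise SimulationError(
        f"could not reach target dS {target_ds} on a {len(cds)}-bp sequence "
        "(sequence too short)"
    )


def _mutate_low_rate(
    seq: str, rate: float, rng: np.random.Generator, coding: bool
) -> str:
    """Per-site substitution at a low rate; in coding mode stop codons
    are never created (the substitution is skipped instead)."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        choices = [b for b in _BASES if b != out[pos]]
        new = choices[int(rng.integers(3))]
        if coding:
            ci = pos // 3
            codon = "".join(out[3 * ci : 3 * ci + 3])
            mutant = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
            if mutant in _STOP_CODONS:
                continue
        out[pos] = new
    return "".join(out)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Cohort simulation


def _true_fixed_sites(gene_id: str, y_cds: str, x_cds_list: list[str]) -> list[FixedDiffSite]:
    sites = []
    for pos, y_base in enumerate(y_cds):
        x_alleles = {x[pos] for x in x_cds_list}
        if len(x_alleles) == 1:
            (x_base,) = x_alleles
            if x_base != y_base:
                sites.append(
                    FixedDiffSite(
                        gene_id=gene_id, column_index=pos, y_allele=y_base, x_allele=x_base
                    )
                )
    return sites


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate gene pairs, chromosome-like templates, and sample genomes.

    Per sex-linked gene: an ancestral CDS is drawn (uniform sense
    codons), the Y copy is mutated to the stratum's target dS, and each X
    haplotype is lightly mutated at ``intra_x_diversity``; an intron is
    inserted at a random codon boundary to form the genomic marker
    sequence.  X haplotype templates share a chromosome backbone
    (spacers); the hemizygous Y template has its own.  Females carry two
    X haplotypes, males one X plus the Y; everyone carries the autosome.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        ss_genes,
        ss_autosomal,
        ss_spacers,
        ss_samples,
    ) = ss.spawn(4)

    gene_seeds = ss_genes.spawn(max(config.n_genes, 1))
    gene_records: list[GeneRecord] = []
    structures: dict[str, GeneStructure] = {}
    y_markers: dict[str, str] = {}
    x_markers: dict[str, list[str]] = {}
    true_sites: dict[str, list[FixedDiffSite]] = {}

    strata = list(config.strata)
    hap_names = [f"hap{h}" for h in range(config.n_x_haplotypes)]

    for g in range(config.n_genes):
        rng = np.random.default_rng(gene_seeds[g])
        gene_id = f"SLG{g:03d}"
        stratum, target_ds = strata[g % len(strata)]
        ancestral = _random_cds(rng, config.gene_length_codons)
        y_cds = mutate_cds(ancestral, target_ds, rng) if target_ds > 0 else ancestral
        x_cds_list = [
            _mutate_low_rate(ancestral, config.intra_x_diversity, rng, coding=True)
            for _ in hap_names
        ]
        intron_at = 3 * int(rng.integers(1, config.gene_length_codons))
        ancestral_intron = _random_dna(rng, config.intron_length_bp)
        y_intron = (
            _mutate_low_rate(ancestral_intron, target_ds, rng, coding=False)
            if config.intron_length_bp
            else ""
        )
        x_introns = [
            _mutate_low_rate(ancestral_intron, config.intra_x_diversity, rng, coding=False)
            for _ in hap_names
        ]
        structures[gene_id] = GeneStructure(
            gene_id=gene_id,
            intron_at_bp=intron_at,
            intron_length_bp=config.intron_length_bp,
        )
        y_markers[gene_id] = y_cds[:intron_at] + y_intron + y_cds[intron_at:]
        x_markers[gene_id] = [
            x[:intron_at] + xi + x[intron_at:] for x, xi in zip(x_cds_list, x_introns)
        ]
        true_sites[gene_id] = _true_fixed_sites(gene_id, y_cds, x_cds_list)
        gene_records.append(
            GeneRecord(
                gene_id=gene_id,
                y_sequence=y_cds,
                x_sequences=[
                    SeqRecord(id=f"{gene_id}|X|{h}", sequence=x, description=f"cultivar {h}")
                    for h, x in zip(hap_names, x_cds_list)
                ],
                stratum=stratum,
                y_expressed=bool(rng.random() < config.y_expressed_fraction),
                intron_length_bp=config.intron_length_bp,
                ds=None,
            )
        )

    # autosomal control genes (identical in every individual)
    rng_a = np.random.default_rng(ss_autosomal)
    autosomal_genes: list[GeneRecord] = []
    auto_markers: list[str] = []
    for g in range(config.n_autosomal_genes):
        gene_id = f"AUT{g:03d}"
        cds = _random_cds(rng_a, config.gene_length_codons)
        intron_at = 3 * int(rng_a.integers(1, config.gene_length_codons))
        intron = _random_dna(rng_a, config.intron_length_bp)
        structures[gene_id] = GeneStructure(
            gene_id=gene_id, intron_at_bp=intron_at, intron_length_bp=config.intron_length_bp
        )
        auto_markers.append(cds[:intron_at] + intron + cds[intron_at:])
        autosomal_genes.append(
            GeneRecord(
                gene_id=gene_id,
                y_sequence=cds,
                x_sequences=[],
                stratum=-1,
                y_expressed=True,
                intron_length_bp=config.intron_length_bp,
            )
        )

    # chromosome-like templates
    rng_s = np.random.default_rng(ss_spacers)
    lo, hi = config.spacer_range_bp
    gene_ids = [g.gene_id for g in gene_records]
    x_spacers = [_random_dna(rng_s, int(rng_s.integers(lo, hi + 1))) for _ in range(len(gene_ids) + 1)]
    y_spacers = [_random_dna(rng_s, int(rng_s.integers(lo, hi + 1))) for _ in range(len(gene_ids) + 1)]
    a_spacers = [
        _random_dna(rng_s, int(rng_s.integers(lo, hi + 1)))
        for _ in range(len(auto_markers) + 1)
    ]

    def _assemble(markers: list[str], spacers: list[str]) -> str:
        parts = []
        for spacer, marker in zip(spacers, markers):
            parts.append(spacer)
            parts.append(marker)
        parts.append(spacers[-1])
        return "".join(parts)

    x_templates = [
        SeqRecord(
            id=f"chrX_{h}",
            sequence=_assemble([x_markers[g][i] for g in gene_ids], x_spacers),
            description=f"X haplotype {h}",
        )
        for i, h in enumerate(hap_names)
    ]
    y_template = SeqRecord(
        id="chrY",
        sequence=_assemble([y_markers[g] for g in gene_ids], y_spacers),
        description="Y haplotype",
    )
    autosome_template = SeqRecord(
        id="autosome", sequence=_assemble(auto_markers, a_spacers), description="autosome"
    )

    # sample genomes
    rng_p = np.random.default_rng(ss_samples)
    samples: list[SampleGenome] = []
    for c in range(config.n_cultivars):
        cultivar = f"cv{c:02d}"
        n = config.n_samples_per_cultivar
        n_males = n // 2 + (1 if (n % 2 and c % 2) else 0)
        sexes = ["male"] * n_males + ["female"] * (n - n_males)
        for k, sex in enumerate(sexes):
            sample_id = f"{cultivar}_s{k:03d}"
            if sex == "male":
                x = x_templates[int(rng_p.integers(len(x_templates)))]
                records = (x, y_template, autosome_template)
            else:
                i, j = rng_p.integers(len(x_templates), size=2)
                # diploid X genotype; a homozygous female carries one
                # distinct X template in her record set
                haps = {x_templates[int(i)].id: x_templates[int(i)]}
                haps.setdefault(x_templates[int(j)].id, x_templates[int(j)])
                records = (*haps.values(), autosome_template)
            samples.append(
                SampleGenome(
                    sample_id=sample_id,
                    cultivar=cultivar,
                    genotypic_sex=sex,
                    records=records,
                )
            )

    return SyntheticCohort(
        config=config,
        gene_records=gene_records,
        structures=structures,
        y_markers=y_markers,
        true_fixed_sites=true_sites,
        autosomal_genes=autosomal_genes,
        x_templates=x_templates,
        y_template=y_template,
        autosome_template=autosome_template,
        samples=samples,
    )


def autosomal_marker(cohort: SyntheticCohort, gene_id: str) -> str:
    """Genomic marker sequence (exon1 + intron + exon2) of an autosomal
    control gene, located on the autosome template."""
    st = cohort.structures[gene_id]
    gene = next(g for g in cohort.autosomal_genes if g.gene_id == gene_id)
    cds = gene.y_sequence
    idx = cohort.autosome_template.sequence.find(cds[: st.intron_at_bp])
    if idx < 0:
        raise SimulationError(f"autosomal marker for {gene_id} not found on template")
    length = len(cds) + st.intron_length_bp
    return cohort.autosome_template.sequence[idx : idx + length]


# ---------------------------------------------------------------------------
# Assay simulation


def simulate_assay(
    panel: MultiplexPanel,
    cohort: SyntheticCohort,
    phenotyping_error_rate: float | None = None,
    seed: int = 0,
    settings: InSilicoSettings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Run the multiplex in silico on every sample and record outcomes.

    Each sample's band pattern is the set of predicted product sizes of
    the three panel pairs on its genome; the recorded phenotypic sex is
    the genotypic truth independently flipped with
    ``phenotyping_error_rate`` (modeling occasional mis-phenotyping or
    sex reversion).  Returns a per-sample results table.
    """
    if phenotyping_error_rate is None:
        phenotyping_error_rate = cohort.config.phenotyping_error_rate
    rng = np.random.default_rng(seed)
    # amplicon sizes are cached per unique template record
    cache: dict[tuple[str, str], list[int]] = {}

    def sizes_for(pair, record: SeqRecord) -> list[int]:
        key = (pair.pair_id, record.id)
        if key not in cache:
            cache[key] = [a.length_bp for a in predict_amplicons(pair, record, settings)]
        return cache[key]

    rows = []
    for sample in cohort.samples:
        observed: list[int] = []
        for pair in panel.members:
            for record in sample.records:
                observed.extend(sizes_for(pair, record))
        result = call_sex(observed, panel)
        pheno = sample.genotypic_sex
        if rng.random() < phenotyping_error_rate:
            pheno = "male" if pheno == "female" else "female"
        rows.append(
            {
                "sample_id": sample.sample_id,
                "cultivar": sample.cultivar,
                "phenotypic_sex": pheno,
                "called_sex": result.call,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk cohort format


def save_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort in the formats the pipeline consumes.

    Layout: ``config.yaml`` (provenance echo), ``genes.fasta`` (CDS of Y,
    X haplotype and autosomal copies), ``gene_metadata.tsv``,
    ``markers.fasta`` (genomic marker sequences), ``templates.fasta``
    (chromosome-like templates), ``truth.json`` (gene structures, true
    fixed sites, per-sample genotypes), ``samples.tsv``, and per-sample
    genome FASTAs under ``genomes/`` with a ``manifest.tsv``.
    """
    import dataclasses
    import json
    from pathlib import Path

    import yaml

    from .sequence_model import write_fasta, write_gene_metadata

    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)

    cfg = dataclasses.asdict(cohort.config)
    cfg["strata"] = [list(s) for s in cohort.config.strata]
    cfg["spacer_range_bp"] = list(cohort.config.spacer_range_bp)
    (out / "config.yaml").write_text(yaml.safe_dump({"simulation": cfg}, sort_keys=True))

    gene_fa = []
    for g in cohort.gene_records:
        gene_fa.append(SeqRecord(id=f"{g.gene_id}|Y", sequence=g.y_sequence))
        gene_fa.extend(g.x_sequences)
    for g in cohort.autosomal_genes:
        gene_fa.append(SeqRecord(id=f"{g.gene_id}|A", sequence=g.y_sequence))
    write_fasta(gene_fa, out / "genes.fasta")
    write_gene_metadata(cohort.gene_records + cohort.autosomal_genes, out / "gene_metadata.tsv")

    marker_fa = [
        SeqRecord(id=f"{gid}|Ymarker", sequence=seq) for gid, seq in cohort.y_markers.items()
    ]
    for g in cohort.autosomal_genes:
        marker_fa.append(
            SeqRecord(id=f"{g.gene_id}|Amarker", sequence=autosomal_marker(cohort, g.gene_id))
        )
    write_fasta(marker_fa, out / "markers.fasta")

    templates = [*cohort.x_templates, cohort.y_template, cohort.autosome_template]
    write_fasta(templates, out / "templates.fasta")

    truth = {
        "structures": {
            gid: {"intron_at_bp": st.intron_at_bp, "intron_length_bp": st.intron_length_bp}
            for gid, st in sorted(cohort.structures.items())
        },
        "fixed_sites": {
            gid: [
                {"column_index": s.column_index, "y_allele": s.y_allele, "x_allele": s.x_allele}
                for s in sites
            ]
            for gid, sites in sorted(cohort.true_fixed_sites.items())
        },
        "sex_linked_gene_ids": [g.gene_id for g in cohort.gene_records],
        "autosomal_gene_ids": [g.gene_id for g in cohort.autosomal_genes],
        "strata": {g.gene_id: g.stratum for g in cohort.gene_records},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    with (out / "samples.tsv").open("w") as fh:
        fh.write("sample_id\tcultivar\tgenotypic_sex\ttemplate_ids\n")
        for s in cohort.samples:
            ids = ",".join(r.id for r in s.records)
            fh.write(f"{s.sample_id}\t{s.cultivar}\t{s.genotypic_sex}\t{ids}\n")

    with (out / "genomes" / "manifest.tsv").open("w") as fh:
        fh.write("genome_id\tfasta_path\texpected_sex\n")
        for s in cohort.samples:
            write_fasta(s.records, out / "genomes" / f"{s.sample_id}.fasta")
            fh.write(f"{s.sample_id}\t{s.sample_id}.fasta\t{s.genotypic_sex}\n")


def load_cohort(cohort_dir) -> SyntheticCohort:
    """Reload a cohort written by :func:`save_cohort`."""
    import json
    from pathlib import Path

    import yaml

    from .sequence_model import read_fasta, read_gene_metadata

    d = Path(cohort_dir)
    cfg = yaml.safe_load((d / "config.yaml").read_text())["simulation"]
    cfg["strata"] = tuple(tuple(s) for s in cfg["strata"])
    cfg["spacer_range_bp"] = tuple(cfg["spacer_range_bp"])
    config = SimulationConfig(**cfg)

    truth = json.loads((d / "truth.json").read_text())
    structures = {
        gid: GeneStructure(gene_id=gid, **st) for gid, st in truth["structures"].items()
    }
    meta = read_gene_metadata(d / "gene_metadata.tsv")

    genes_by_id: dict[str, dict] = {}
    for rec in read_fasta(d / "genes.fasta"):
        parts = rec.id.split("|")
        entry = genes_by_id.setdefault(parts[0], {"x": []})
        if parts[1] == "Y" or parts[1] == "A":
            entry["main"] = rec.sequence
        else:
            entry["x"].append(rec)

    def build(gid: str) -> GeneRecord:
        m = meta[gid]
        return GeneRecord(
            gene_id=gid,
            y_sequence=genes_by_id[gid]["main"],
            x_sequences=genes_by_id[gid]["x"],
            stratum=m["stratum"],
            y_expressed=m["y_expressed"],
            intron_length_bp=m["intron_length_bp"],
        )

    gene_records = [build(g) for g in truth["sex_linked_gene_ids"]]
    autosomal_genes = [build(g) for g in truth["autosomal_gene_ids"]]

    y_markers = {}
    for rec in read_fasta(d / "markers.fasta"):
        gid, kind = rec.id.split("|")
        if kind == "Ymarker":
            y_markers[gid] = rec.sequence

    fixed_sites = {
        gid: [FixedDiffSite(gene_id=gid, **s) for s in sites]
        for gid, sites in truth["fixed_sites"].items()
    }

    templates = {r.id: r for r in read_fasta(d / "templates.fasta")}
    x_templates = [templates[tid] for tid in sorted(templates) if tid.startswith("chrX")]

    samples = []
    with (d / "samples.tsv").open() as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            sample_id, cultivar, sex, ids = line.rstrip("\n").split("\t")
            samples.append(
                SampleGenome(
                    sample_id=sample_id,
                    cultivar=cultivar,
                    genotypic_sex=sex,
                    records=tuple(templates[t] for t in ids.split(",")),
                )
            )

    return SyntheticCohort(
        config=config,
        gene_records=gene_records,
        structures=structures,
        y_markers=y_markers,
        true_fixed_sites=fixed_sites,
        autosomal_genes=autosomal_genes,
        x_templates=x_templates,
        y_template=templates["autosome"] if "chrY" not in templates else templates["chrY"],
        autosome_template=templates["autosome"],
        samples=samples,
    )
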