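from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_codon_diffs, oracle_codon_sites, oracle_ng86_ds
from ymarker.divergence import (
    CodingSequenceError,
    count_codon_diffs,
    count_codon_sites,
    call_fixed_differences,
    nei_gojobori_ds,
    select_candidate_genes,
)
from ymarker.sequence_model import GeneRecord, SeqRecord

SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class TestCodonSites:
    @pytest.mark.parametrize(
        "codon,expected_syn",
        [("TTT", 1 / 3), ("ATG", 0.0), ("GGG", 1.0)],
    )
    def test_known_codons(self, codon, expected_syn):
        syn, nonsyn = count_codon_sites(codon)
        assert syn == pytest.approx(expected_syn)
        assert syn + nonsyn == pytest.approx(3.0)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE:
            assert count_codon_sites(codon)[0] == pytest.approx(oracle_codon_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(CodingSequenceError):
            count_codon_sites("TAA")

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(CodingSequenceError):
            count_codon_sites("ANT")


class TestCodonDiffs:
    def test_matches_pathway_oracle_on_all_multi_hit_pairs(self, rng):
        picks = rng.choice(len(SENSE), size=(300, 2))
        for i, j in picks:
            ca, cb = SENSE[int(i)], SENSE[int(j)]
            assert count_codon_diffs(ca, cb) == pytest.approx(oracle_codon_diffs(ca, cb))

    def test_total_diffs_equal_hamming(self, rng):
        picks = rng.choice(len(SENSE), size=(100, 2))
        for i, j in picks:
            ca, cb = SENSE[int(i)], SENSE[int(j)]
            sd, nd = count_codon_diffs(ca, cb)
            assert sd + nd == sum(x != y for x, y in zip(ca, cb))


class TestNeiGojobori:
    def test_identical_sequences(self):
        cds = "".join(SENSE[:50])
        est = nei_gojobori_ds(cds, cds)
        assert est.ds == 0.0 and est.dn == 0.0

    def test_single_synonymous_difference_closed_form(self, rng):
        codons = [SENSE[int(i)] for i in rng.choice(len(SENSE), size=300)]
        a = "".join(codons)
        # GGG -> GGA at codon 10 is synonymous (Gly)
        codons[10] = "GGG"
        a = "".join(codons)
        codons[10] = "GGA"
        b = "".join(codons)
        est = nei_gojobori_ds(a, b)
        s = (sum(count_codon_sites(c)[0] for c in a_codons(a)) +
             sum(count_codon_sites(c)[0] for c in a_codons(b))) / 2
        ps = 1.0 / s
        assert est.syn_diffs == pytest.approx(1.0)
        assert est.ps == pytest.approx(ps)
        assert est.ds == pytest.approx(-0.75 * math.log(1 - 4 / 3 * ps))

    def test_matches_independent_oracle_on_random_pairs(self, rng):
        for _ in range(10):
            a = "".join(SENSE[int(i)] for i in rng.choice(len(SENSE), size=30))
            b = list(a)
            # random substitutions avoiding stops
            for pos in rng.choice(len(a), size=12, replace=False):
                for base in "ACGT":
                    ci = pos // 3
                    cand = b[:]
                    cand[pos] = base
                    codon = "".join(cand[3 * ci : 3 * ci + 3])
                    if codon not in ("TAA", "TAG", "TGA") and base != b[pos]:
                        b = cand
                        break
            b = "".join(b)
            expected = oracle_ng86_ds(a, b)
            got = nei_gojobori_ds(a, b).ds
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_symmetry(self, rng):
        a = "".join(SENSE[int(i)] for i in rng.choice(len(SENSE), size=40))
        b = "".join(SENSE[int(i)] for i in rng.choice(len(SENSE), size=40))
        ea, eb = nei_gojobori_ds(a, b), nei_gojobori_ds(b, a)
        assert ea.syn_diffs == pytest.approx(eb.syn_diffs)
        assert ea.syn_sites == pytest.approx(eb.syn_sites)

    def test_sites_sum_to_three_per_codon(self, rng):
        a = "".join(SENSE[int(i)] for i in rng.choice(len(SENSE), size=60))
        est = nei_gojobori_ds(a, a)
        assert est.syn_sites + est.nonsyn_sites == pytest.approx(3 * est.n_codons)

    def test_monotone_in_synonymous_differences(self):
        base = "GGGTTTAAACCC" * 25  # Gly Phe Lys Pro x 25
        prev = -1.0
        seq = list(base)
        estimates = []
        for k in range(0, 10):
            est = nei_gojobori_ds(base, "".join(seq))
            estimates.append(est.ds)
            # introduce one more synonymous change (GGG -> GGA)
            seq[12 * k + 2] = "A"
        assert all(b > a for a, b in zip(estimates, estimates[1:]))

    def test_gapped_codons_dropped_pairwise(self):
        est = nei_gojobori_ds("GGG---AAA", "GGGTTTAAA")
        assert est.n_codons == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(CodingSequenceError):
            nei_gojobori_ds("GGGAAA", "GGG")

    def test_premature_stop_rejected(self):
        with pytest.raises(CodingSequenceError):
            nei_gojobori_ds("TAAGGGAAA", "TACGGGAAA")

    def test_terminal_stop_tolerated(self):
        est = nei_gojobori_ds("GGGAAATAA", "GGGAAATGA")
        assert est.n_codons == 2

    def test_saturation_flag(self):
        est = nei_gojobori_ds("GGA", "GGG")  # 1 syn diff over ~1 syn site
        assert est.ds_saturated and math.isnan(est.ds)


def a_codons(seq):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


class TestFixedDifferences:
    def _rec(self, seq, rid="y"):
        return SeqRecord(id=rid, sequence=seq)

    def test_no_divergence(self):
        with pytest.warns(UserWarning):
            sites = call_fixed_differences(self._rec("ACGT"), [self._rec("ACGT", "x")])
        assert sites == []

    def test_fixed_site_called(self):
        y = self._rec("ACGTACGTACGT")
        xs = [self._rec("ACGTACGTACGT".replace("T", "T"), f"x{i}") for i in range(3)]
        xs = [SeqRecord(id=f"x{i}", sequence="ACGAACGTACGT") for i in range(3)]
        sites = call_fixed_differences(y, xs)
        assert len(sites) == 1
        site = sites[0]
        assert (site.column_index, site.y_allele, site.x_allele) == (3, "T", "A")

    def test_polymorphic_in_x_not_called(self):
        y = self._rec("ACGTACGT")
        xs = [
            SeqRecord(id="x0", sequence="ACGGACGT"),
            SeqRecord(id="x1", sequence="ACGGACGT"),
            SeqRecord(id="x2", sequence="ACGTACGT"),  # shares Y allele
        ]
        assert call_fixed_differences(y, xs) == []

    def test_single_x_equals_mismatch_columns(self, rng):
        y_seq = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=60))
        x = list(y_seq)
        for pos in (5, 20, 40):
            x[pos] = "ACGT"[("ACGT".index(x[pos]) + 1) % 4]
        with pytest.warns(UserWarning):
            sites = call_fixed_differences(
                SeqRecord(id="y", sequence=y_seq),
                [SeqRecord(id="x", sequence="".join(x))],
            )
        assert [s.column_index for s in sites] == [5, 20, 40]

    def test_empty_x_set_rejected(self):
        with pytest.raises(ValueError):
            call_fixed_differences(self._rec("ACGT"), [])


def _gene(gene_id, ds, stratum=0, y_expressed=True, intron=400):
    return GeneRecord(
        gene_id=gene_id,
        y_sequence="ATGGGGAAA",
        x_sequences=[],
        stratum=stratum,
        y_expressed=y_expressed,
        intron_length_bp=intron,
        ds=ds,
    )


class TestSelectCandidateGenes:
    def test_not_expressed_excluded(self):
        genes = [_gene("a", 0.5, y_expressed=False), _gene("b", 0.1)]
        assert [g.gene_id for g in select_candidate_genes(genes)] == ["b"]

    def test_short_intron_excluded(self):
        genes = [_gene("a", 0.5, intron=250), _gene("b", 0.1)]
        assert [g.gene_id for g in select_candidate_genes(genes)] == ["b"]

    def test_younger_stratum_excluded(self):
        genes = [_gene("a", 0.5, stratum=1), _gene("b", 0.1, stratum=0)]
        assert [g.gene_id for g in select_candidate_genes(genes)] == ["b"]

    def test_top_k_by_ds_matches_sort_oracle(self, rng):
        ds_values = rng.permutation(np.linspace(0.01, 0.6, 30))
        genes = [_gene(f"g{i:02d}", float(ds)) for i, ds in enumerate(ds_values)]
        picked = select_candidate_genes(genes, top_k=20)
        expected = sorted(genes, key=lambda g: -g.ds)[:20]
        assert {g.gene_id for g in picked} == {g.gene_id for g in expected}

    def test_never_more_than_top_k_and_idempotent(self):
        genes = [_gene(f"g{i}", 0.01 * i) for i in range(30)]
        once = select_candidate_genes(genes, top_k=5)
        assert len(once) <= 5
        assert select_candidate_genes(once, top_k=5) == once

    def test_missing_ds_named(self):
        with pytest.raises(ValueError, match="gX"):
            select_candidate_genes([_gene("gX", None)])

    def test_saturated_ds_ranked_last(self):
        genes = [_gene("sat", float("nan")), _gene("a", 0.2), _gene("b", 0.1)]
        picked = select_candidate_genes(genes, top_k=2)
        assert [g.gene_id for g in picked] == ["a", "b"]
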