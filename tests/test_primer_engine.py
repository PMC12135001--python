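from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_dimer, oracle_tm_nn
from ymarker.divergence import FixedDiffSite
from ymarker.primer_engine import (
    DEFAULT_CONSTRAINTS,
    MultiplexInfeasibleError,
    MultiplexPanel,
    Primer,
    PrimerConstraints,
    PrimerDesignError,
    PrimerPair,
    dimer_reject,
    dimer_score,
    enumerate_candidates,
    gc_content,
    melting_temp,
    passes_qc,
    select_multiplex,
    wallace_tm,
)
from ymarker.sequence_model import GeneRecord, reverse_complement

dna20 = st.text(alphabet="ACGT", min_size=20, max_size=20)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGCC", 1.0),
            ("GTTATATGGACATGGACTCT", 0.40),
            ("AAAAGGGGTGAAAAGGTG", 8 / 18),
        ],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(PrimerDesignError):
            gc_content("")


class TestMeltingTemp:
    def test_gc_rich_melts_higher(self):
        assert melting_temp("GCGCGCGCGCGCGCGC") > melting_temp("ATATATATATATATAT")

    def test_matches_hand_entered_nn_table(self, published_primers):
        for row in published_primers.values():
            for seq in (row.forward_seq, row.reverse_seq):
                assert melting_temp(seq, 50.0, 0.25) == pytest.approx(
                    oracle_tm_nn(seq, 50.0, 250.0), abs=0.5
                )

    def test_wallace_rule_cross_check(self):
        assert wallace_tm("GTTATATGGACATGGACTCT") == 56.0

    def test_length_bounds(self):
        with pytest.raises(PrimerDesignError):
            melting_temp("ACGTACGTACGT")  # 12 nt


class TestDimerScore:
    def test_perfect_self_complement(self):
        p = "ACGTACGTACGTACGTAC"
        run, _ = dimer_score(p, reverse_complement(p))
        assert run == len(p)

    def test_homopolymer_complement(self):
        assert dimer_score("A" * 18, "T" * 18)[0] == 18

    @given(dna20, dna20)
    @settings(max_examples=100, deadline=None)
    def test_matches_all_offsets_oracle(self, s1, s2):
        assert dimer_score(s1, s2) == oracle_dimer(s1, s2)

    @given(dna20, dna20)
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, s1, s2):
        assert dimer_score(s1, s2) == dimer_score(s2, s1)

    @given(dna20, dna20)
    @settings(max_examples=100, deadline=None)
    def test_reject_shortcut_equivalent_to_thresholds(self, s1, s2):
        run, three = dimer_score(s1, s2)
        assert dimer_reject(s1, s2, 8, 4) == (run >= 8 or three >= 4)


def _mk_gene(seq, gene_id="G1"):
    return GeneRecord(gene_id=gene_id, y_sequence=seq, x_sequences=[])


def _sites(gene_id, positions, template):
    out = []
    for pos in positions:
        y = template[pos]
        x = {"A": "G", "G": "A", "C": "T", "T": "C"}[y]
        out.append(FixedDiffSite(gene_id=gene_id, column_index=pos, y_allele=y, x_allele=x))
    return out


@pytest.fixture(scope="module")
def design_template():
    import numpy as np

    rng = np.random.default_rng(123)
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=600))


class TestEnumerateCandidates:
    def test_no_fixed_sites_no_y_candidates(self, design_template):
        gene = _mk_gene(design_template)
        assert enumerate_candidates(gene, [], target_type="y_specific") == []

    def test_amplicons_cover_both_sites(self, design_template):
        gene = _mk_gene(design_template)
        sites = _sites("G1", [200, 350], design_template)
        pairs = enumerate_candidates(gene, sites, target_type="y_specific")
        for p in pairs:
            assert p.forward_start <= 200 and p.reverse_end > 350
            assert p.n_fixed_diffs_covered == 2

    def test_anchor_rule_enforced(self, design_template):
        gene = _mk_gene(design_template)
        sites = _sites("G1", [200, 350], design_template)
        k = DEFAULT_CONSTRAINTS.anchor_3prime_nt
        for p in enumerate_candidates(gene, sites, target_type="y_specific"):
            anchored = [
                off
                for primer in (p.forward, p.reverse)
                for _, off in primer.anchor_sites
                if off < k
            ]
            assert anchored, p.pair_id

    def test_matches_brute_force_double_loop(self, design_template):
        template = design_template[:300]
        gene = _mk_gene(template)
        sites = _sites("G1", [90, 180], template)
        c = DEFAULT_CONSTRAINTS
        got = {
            (p.forward_start, len(p.forward), p.reverse_end - len(p.reverse), len(p.reverse))
            for p in enumerate_candidates(gene, sites, c, "y_specific")
        }
        site_pos = [90, 180]

        # per-window QC table computed once, then an exhaustive double loop
        def window_ok(start, length, orientation):
            seq = template[start : start + length]
            if orientation == "reverse":
                seq = reverse_complement(seq)
            if not (c.gc_min <= gc_content(seq) <= c.gc_max):
                return None
            if not (c.tm_min <= melting_temp(seq) <= c.tm_max):
                return None
            run, three = dimer_score(seq, seq)
            if run >= c.max_comp_run or three >= c.max_three_prime_run:
                return None
            return seq

        fwd_ok, rev_ok = [], []
        for length in range(c.len_min, c.len_max + 1):
            for start in range(0, len(template) - length + 1):
                f_seq = window_ok(start, length, "forward")
                if f_seq is not None:
                    fwd_ok.append((start, length, f_seq))
                r_seq = window_ok(start, length, "reverse")
                if r_seq is not None:
                    rev_ok.append((start, length, r_seq))

        expected = set()
        for f_start, f_len, f_seq in fwd_ok:
            for r_start, r_len, r_seq in rev_ok:
                if r_start < f_start + f_len:
                    continue
                amp = r_start + r_len - f_start
                if not c.amp_min <= amp <= c.amp_max:
                    continue
                covered = [p for p in site_pos if f_start <= p < r_start + r_len]
                if len(covered) < 2:
                    continue
                f_anch = any(
                    f_start <= p < f_start + f_len
                    and (f_start + f_len - 1 - p) < c.anchor_3prime_nt
                    for p in site_pos
                )
                r_anch = any(
                    r_start <= p < r_start + r_len and (p - r_start) < c.anchor_3prime_nt
                    for p in site_pos
                )
                if not (f_anch or r_anch):
                    continue
                run, three = dimer_score(f_seq, r_seq)
                if run >= c.max_comp_run or three >= c.max_three_prime_run:
                    continue
                expected.add((f_start, f_len, r_start, r_len))
        assert got == expected

    def test_site_order_invariance(self, design_template):
        gene = _mk_gene(design_template)
        sites = _sites("G1", [150, 220, 380], design_template)
        a = enumerate_candidates(gene, sites)
        b = enumerate_candidates(gene, list(reversed(sites)))
        assert a == b

    def test_tighter_constraints_shrink_output(self, design_template):
        gene = _mk_gene(design_template)
        sites = _sites("G1", [200, 350], design_template)
        loose = enumerate_candidates(gene, sites, DEFAULT_CONSTRAINTS)
        import dataclasses

        tight_c = dataclasses.replace(DEFAULT_CONSTRAINTS, tm_min=57.0, tm_max=60.0)
        tight = enumerate_candidates(gene, sites, tight_c)
        loose_keys = {p.pair_id for p in loose}
        assert {p.pair_id for p in tight} <= loose_keys


class TestPublishedPrimerQC:
    def test_all_published_primers_pass_default_qc(self, published_primers):
        relaxed = PrimerConstraints(len_min=18, len_max=20)
        for row in published_primers.values():
            for seq in (row.forward_seq, row.reverse_seq):
                assert passes_qc(seq, relaxed), seq

    def test_published_gc_fractions(self, published_primers):
        assert gc_content(published_primers["23"].forward_seq) == pytest.approx(0.40)
        assert gc_content(published_primers["36"].forward_seq) == pytest.approx(8 / 18)

    def test_published_amplicon_sizes_gel_compatible(self, published_primers):
        sizes = sorted(row.amplicon_bp for row in published_primers.values())
        assert sizes == [174, 300, 514]
        gaps = [b - a for a, b in zip(sizes, sizes[1:])]
        assert min(gaps) >= 100  # 126 and 214


def _pair(pair_id, gene_id, amp, n_cov=2, target_type="y_specific", fseq=None, rseq=None):
    # purine-only oligos cannot base-pair with each other, so dimer
    # filters never interfere with the size/coverage logic under test
    fseq = fseq or "AAAGAAAGAAAGAAAGAA"
    rseq = rseq or "AAGAAAGAAAGAAAGAAA"
    mk = lambda s, o: Primer(
        sequence=s,
        gene_id=gene_id,
        orientation=o,
        tm_c=58.0,
        gc_fraction=(s.count("G") + s.count("C")) / len(s),
    )
    return PrimerPair(
        pair_id=pair_id,
        forward=mk(fseq, "forward"),
        reverse=mk(rseq, "reverse"),
        expected_amplicon_bp=amp,
        target_type=target_type,
        n_fixed_diffs_covered=n_cov if target_type == "y_specific" else 0,
    )


class TestSelectMultiplex:
    def test_published_size_triplet_feasible(self):
        y1 = _pair("p23", "gA", 174)
        y2 = _pair("p36", "gB", 300)
        ctrl = _pair("p9", "gC", 514, target_type="autosomal_control")
        panel = select_multiplex([y1, y2], [ctrl], min_size_gap_bp=100)
        assert sorted(panel.amplicon_sizes) == [174, 300, 514]

    def test_single_gene_infeasible(self):
        y1 = _pair("a", "gA", 174)
        y2 = _pair("b", "gA", 300)
        ctrl = _pair("c", "gC", 514, target_type="autosomal_control")
        with pytest.raises(MultiplexInfeasibleError, match="distinct genes"):
            select_multiplex([y1, y2], [ctrl])

    def test_size_gap_infeasibility_reported(self):
        y1 = _pair("a", "gA", 200)
        y2 = _pair("b", "gB", 210)
        ctrl = _pair("c", "gC", 500, target_type="autosomal_control")
        with pytest.raises(MultiplexInfeasibleError, match="size_gap"):
            select_multiplex([y1, y2], [ctrl], min_size_gap_bp=60)

    def test_matches_exhaustive_oracle_on_small_instance(self):
        ys = [
            _pair(f"y{i}", f"g{i % 3}", 150 + 40 * i, n_cov=2 + (i % 4)) for i in range(6)
        ]
        ctrls = [
            _pair(f"c{i}", "gc", 480 + 70 * i, target_type="autosomal_control")
            for i in range(2)
        ]
        panel = select_multiplex(ys, ctrls, min_size_gap_bp=60)

        best = None
        for y1, y2 in itertools.combinations(ys, 2):
            if y1.gene_id == y2.gene_id:
                continue
            for ctrl in ctrls:
                sizes = sorted(
                    [y1.expected_amplicon_bp, y2.expected_amplicon_bp, ctrl.expected_amplicon_bp]
                )
                if any(b - a < 60 for a, b in zip(sizes, sizes[1:])):
                    continue
                dimer_total = 0
                ok = True
                for a, b in itertools.combinations((y1, y2, ctrl), 2):
                    for p, q in itertools.product(
                        (a.forward, a.reverse), (b.forward, b.reverse)
                    ):
                        run, three = dimer_score(p, q)
                        if run >= 8 or three >= 4:
                            ok = False
                        dimer_total += run + three
                if not ok:
                    continue
                key = (
                    -(y1.n_fixed_diffs_covered + y2.n_fixed_diffs_covered),
                    dimer_total,
                    tuple(sorted((y1.gene_id, y2.gene_id))),
                    ctrl.gene_id,
                    y1.pair_id,
                    y2.pair_id,
                    ctrl.pair_id,
                )
                if best is None or key < best[0]:
                    best = (key, {y1.pair_id, y2.pair_id, ctrl.pair_id})
        assert best is not None
        got_ids = {p.pair_id for p in panel.members}
        assert got_ids == best[1]

    def test_panel_invariants_enforced(self):
        y1 = _pair("a", "gA", 174)
        ctrl = _pair("c", "gC", 514, target_type="autosomal_control")
        with pytest.raises(ValueError):
            MultiplexPanel(y_pairs=(y1, y1), control_pair=ctrl, min_size_gap_bp=60)
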