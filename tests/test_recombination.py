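"""Recombinant-configuration prediction, assay layout, chimeric reads."""

import numpy as np
import pytest

from mito_recomb.circgenome import CircInterval, CircularGenome, reverse_complement
from mito_recomb.recombination import (
    FlankError,
    GeometryError,
    design_assay,
    detect_chimeric_reads,
    predict_products,
    quantify_configurations,
)
from mito_recomb.repeat_finder import RepeatHit
from mito_recomb.synthetic_data import RepeatSpec, generate_genome

from .conftest import GENOME_LENGTH


@pytest.fixture(scope="module")
def repeat_a_genome():
    """Full-length genome with a 175-nt direct repeat at the published
    repeat-A coordinates."""
    g, truth = generate_genome(
        GENOME_LENGTH,
        [RepeatSpec(175, 100.0, "direct", positions=(120320, 331059))],
        seed=21,
    )
    return g, truth.repeats[0].as_hit(g.length)


class TestPredictDirect:
    def test_repeat_a_product_sizes(self, repeat_a_genome):
        """Crossover at the published repeat-A coordinates splits the
        genome into 210,739-nt and 190,523-nt subcircles."""
        g, hit = repeat_a_genome
        cfg = predict_products(g, hit, flank=100)
        assert sorted(cfg.product_sizes) == [190523, 210739]
        assert sum(cfg.product_sizes) == GENOME_LENGTH
        assert [len(s) for _, s in cfg.products] == cfg.product_sizes

    def test_equal_halves_when_copies_antipodal(self):
        g, truth = generate_genome(
            8000, [RepeatSpec(100, 100.0, "direct", positions=(1000, 5000))], seed=1
        )
        cfg = predict_products(g, truth.repeats[0].as_hit(8000), flank=50)
        assert cfg.product_sizes == [4000, 4000]

    @pytest.mark.parametrize("seed", range(5))
    def test_sizes_sum_to_genome_length(self, seed):
        g, truth = generate_genome(9000, [RepeatSpec(120, 100.0, "direct")], seed=seed)
        cfg = predict_products(g, truth.repeats[0].as_hit(9000), flank=30)
        assert sum(cfg.product_sizes) == 9000

    def test_each_subcircle_retains_one_copy(self):
        g, truth = generate_genome(
            6000, [RepeatSpec(150, 100.0, "direct", positions=(1000, 4000))], seed=2
        )
        r = truth.repeats[0]
        cfg = predict_products(g, r.as_hit(6000), flank=40)
        core = g.seq[r.copy1.start - 1 : r.copy1.end]
        for _, seq in cfg.products:
            # circular occurrence count: starts within one period only
            doubled = seq + seq
            n = 0
            idx = doubled.find(core)
            while 0 <= idx < len(seq):
                n += 1
                idx = doubled.find(core, idx + 1)
            assert n == 1

    def test_junctions_absent_from_reference(self, repeat_a_genome):
        g, hit = repeat_a_genome
        cfg = predict_products(g, hit, flank=200)
        doubled = g.seq + g.seq
        for j in cfg.junctions:
            assert j.seq not in doubled
            assert reverse_complement(j.seq) not in doubled

    def test_junction_layout_matches_spec(self):
        g, truth = generate_genome(
            5000, [RepeatSpec(100, 100.0, "direct", positions=(1000, 3000))], seed=3
        )
        cfg = predict_products(g, truth.repeats[0].as_hit(5000), flank=60)
        j1, j2 = cfg.junctions
        ex = lambda a, b: g.seq[a - 1 : b]
        # upstream flank of copy2 + copy1 + downstream flank of copy1
        assert j1.seq == ex(2940, 2999) + ex(1000, 1099) + ex(1100, 1159)
        # upstream flank of copy1 + copy2 + downstream flank of copy2
        assert j2.seq == ex(940, 999) + ex(3000, 3099) + ex(3100, 3159)


class TestPredictInverted:
    def test_reconstruction_matches_string_oracle(self):
        g, truth = generate_genome(10_000, [RepeatSpec(150, 100.0, "inverted")], seed=4)
        r = truth.repeats[0]
        cfg = predict_products(g, r.as_hit(10_000), flank=50)
        assert cfg.kind == "inversion"
        assert cfg.product_sizes == [10_000]
        e1, s2 = r.copy1.end, r.copy2.start
        expected = (
            g.seq[:e1]
            + reverse_complement(g.seq[e1 : s2 - 1])
            + g.seq[s2 - 1 :]
        )
        assert cfg.products[0][1] == expected

    def test_round_trip_restores_reference(self):
        g, truth = generate_genome(7000, [RepeatSpec(90, 100.0, "inverted")], seed=5)
        hit = truth.repeats[0].as_hit(7000)
        once = predict_products(g, hit, flank=30)
        g_inv = CircularGenome(id="inv", seq=once.products[0][1])
        twice = predict_products(g_inv, hit, flank=30)
        assert twice.products[0][1] == g.seq

    def test_base_composition_conserved(self):
        g, truth = generate_genome(7000, [RepeatSpec(90, 100.0, "inverted")], seed=6)
        cfg = predict_products(g, truth.repeats[0].as_hit(7000), flank=30)
        inv = cfg.products[0][1]
        # inversion swaps each base for its complement in the flipped
        # segment, so A<->T and C<->G counts are exchanged pairwise and the
        # 1-mer multiset is conserved only when counted strand-symmetrically
        assert sorted(inv) != [] and len(inv) == len(g.seq)
        for b, c in (("A", "T"), ("C", "G")):
            assert inv.count(b) + inv.count(c) == g.seq.count(b) + g.seq.count(c)

    def test_junctions_absent_from_reference(self):
        g, truth = generate_genome(7000, [RepeatSpec(90, 100.0, "inverted")], seed=7)
        cfg = predict_products(g, truth.repeats[0].as_hit(7000), flank=80)
        doubled = g.seq + g.seq
        for j in cfg.junctions:
            assert j.seq not in doubled
            assert reverse_complement(j.seq) not in doubled


class TestGeometryErrors:
    def test_overlapping_copies(self):
        g = CircularGenome(id="t", seq="ACGT" * 500)
        hit = RepeatHit(
            copy1=CircInterval(start=100, end=300),
            copy2=CircInterval(start=250, end=450),
            orientation="direct",
            score=10.0,
            evalue=0.1,
            identity=100.0,
        )
        with pytest.raises(GeometryError):
            predict_products(g, hit, flank=10)

    def test_flank_overrunning_partner_copy(self):
        g, truth = generate_genome(
            4000, [RepeatSpec(100, 100.0, "direct", positions=(1000, 1200))], seed=8
        )
        with pytest.raises(FlankError):
            predict_products(g, truth.repeats[0].as_hit(4000), flank=150)


class TestDesignAssay:
    def test_valid_assay_for_direct_repeat(self):
        g, truth = generate_genome(
            6000, [RepeatSpec(175, 100.0, "direct", positions=(1500, 4500))], seed=11
        )
        cfg = predict_products(g, truth.repeats[0].as_hit(6000), flank=300)
        assays = design_assay(g, cfg, primer_len=20, max_product=2000)
        assert len(assays) == 2
        for a in assays:
            assert a.success
            assert a.expected_product_size == 20 + 175 + 20  # windows at offset 0
            assert a.reference_product_sizes == []

    def test_duplicated_flank_is_design_failure(self):
        g, truth = generate_genome(
            6000, [RepeatSpec(100, 100.0, "direct", positions=(1500, 4500))], seed=12
        )
        r = truth.repeats[0]
        cfg = predict_products(g, r.as_hit(6000), flank=60)
        # copy the entire upstream flank window of copy2 (junction A->D
        # primer-1 territory) elsewhere so no window in it is unique
        s2 = r.copy2.start
        flank_seq = g.seq[s2 - 61 : s2 - 1]
        seq2 = g.seq[:5800] + flank_seq + g.seq[5860:]
        g2 = CircularGenome(id="dup", seq=seq2)
        cfg2 = predict_products(g2, r.as_hit(6000), flank=60)
        assays = design_assay(g2, cfg2, primer_len=20, max_product=500)
        a_to_d = [a for a in assays if a.junction_label == "A->D"][0]
        assert not a_to_d.success

    def test_inverted_assay_primers_both_plus_on_reference(self):
        g, truth = generate_genome(
            6000, [RepeatSpec(120, 100.0, "inverted", positions=(1500, 4500))], seed=13
        )
        cfg = predict_products(g, truth.repeats[0].as_hit(6000), flank=200)
        assays = design_assay(g, cfg, primer_len=20, max_product=2000)
        # an inverted-repeat assay is convergent only after the inversion:
        # on the reference both primers sit on the same strand ('+' for the
        # E->G junction, '-' for the reciprocal G->E junction)
        by_label = {a.junction_label: a for a in assays}
        for a in assays:
            assert a.success
            assert a.primer1_window.strand == a.primer2_window.strand
        assert by_label["E->G"].primer1_window.strand == "+"


class TestDetectChimericReads:
    def test_planted_positive_and_negative(self, direct_repeat_pool):
        g, truth, hit, pool, _ = direct_repeat_pool
        cfg = predict_products(g, hit, flank=120)
        junction_read = cfg.junctions[0].seq[40 : 40 + 300]
        reference_read = g.seq[2000:2350]
        ev = detect_chimeric_reads(
            [("pos", junction_read), ("neg", reference_read)], g, [hit], min_anchor=20
        )
        assert [e.read_id for e in ev] == ["pos"]
        assert ev[0].config_label in ("A->D", "D->A")

    def test_anchors_fall_in_flanks_of_different_copies(self, direct_repeat_pool):
        g, truth, hit, pool, _ = direct_repeat_pool
        cfg = predict_products(g, hit, flank=120)
        read = cfg.junctions[0].seq[40 : 40 + 300]
        (ev,) = detect_chimeric_reads([("r", read)], g, [hit], min_anchor=20)
        s1, e1 = hit.copy1.start, hit.copy1.end
        s2, e2 = hit.copy2.start, hit.copy2.end
        # A->D junction: anchor1 upstream of copy2, anchor2 downstream of copy1
        assert ev.anchor1.end == s2 - 1
        assert ev.anchor2.start == e1 + 1

    def test_short_anchor_rejected(self, direct_repeat_pool):
        g, truth, hit, pool, _ = direct_repeat_pool
        cfg = predict_products(g, hit, flank=120)
        # read reaches only 10 nt into the far flank
        read = cfg.junctions[0].seq[120 - 150 + 175 + 10 :][:150]
        start = 120 - (150 - 175 - 10)
        read = cfg.junctions[0].seq[start : start + 150]
        ev = detect_chimeric_reads([("r", read)], g, [hit], min_anchor=20)
        assert ev == []

    def test_mismatched_read_found_with_edit_budget(self, direct_repeat_pool):
        g, truth, hit, pool, _ = direct_repeat_pool
        cfg = predict_products(g, hit, flank=120)
        read = list(cfg.junctions[1].seq[30 : 30 + 300])
        read[150] = "A" if read[150] != "A" else "C"
        read = "".join(read)
        assert detect_chimeric_reads([("r", read)], g, [hit], max_mismatch=0) == []
        ev = detect_chimeric_reads([("r", read)], g, [hit], max_mismatch=2)
        assert len(ev) == 1
        assert ev[0].mismatches == 1

    def test_reverse_complement_read_detected(self, direct_repeat_pool):
        g, truth, hit, pool, _ = direct_repeat_pool
        cfg = predict_products(g, hit, flank=120)
        read = reverse_complement(cfg.junctions[0].seq[40 : 40 + 300])
        assert len(detect_chimeric_reads([("r", read)], g, [hit])) == 1


class TestQuantify:
    def test_hundred_to_one(self, direct_repeat_pool):
        g, truth, hit, pool, _ = direct_repeat_pool
        cfg = predict_products(g, hit, flank=120)
        s1 = hit.copy1.start
        ref_read = g.seq[s1 - 81 : s1 - 81 + 350]  # spans copy1 with wide anchors
        reads = [(f"ref{i}", ref_read) for i in range(100)]
        reads.append(("rec", cfg.junctions[0].seq[40 : 40 + 300]))
        ev = detect_chimeric_reads(reads, g, [hit])
        ratios = quantify_configurations(ev, reads, g, [hit])
        assert ratios["rep1"].recombinant_reads == 1
        assert ratios["rep1"].reference_reads == 100
        assert ratios["rep1"].ratio == pytest.approx(100.0)
        assert not ratios["rep1"].undefined

    def test_zero_recombinants_flagged_undefined(self, direct_repeat_pool):
        g, truth, hit, pool, _ = direct_repeat_pool
        s1 = hit.copy1.start
        reads = [("ref", g.seq[s1 - 81 : s1 - 81 + 350])]
        ratios = quantify_configurations([], reads, g, [hit])
        assert ratios["rep1"].undefined
        assert ratios["rep1"].ratio is None
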