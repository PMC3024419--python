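"""Surrogate repeats and the PCR template-switching simulator."""

import numpy as np
import pytest

from mito_recomb.circgenome import CircularGenome, extract, reverse_complement
from mito_recomb.pcr_recomb import (
    PcrPool,
    PcrTemplate,
    PrimerDesignError,
    bispecies_pool,
    concentration_response,
    expected_chimeric_products,
    find_surrogate_repeats,
    simulate_pcr,
)
from mito_recomb.synthetic_data import generate_bispecies_fixture

SHARED_LENGTHS = [55, 90, 148, 639]
SHARED_IDENTITIES = [100.0, 100.0, 94.0, 99.0]


@pytest.fixture(scope="module")
def bispecies():
    gA, gB, truth = generate_bispecies_fixture(
        SHARED_LENGTHS, SHARED_IDENTITIES, seed=9
    )
    return gA, gB, truth


@pytest.fixture(scope="module")
def surrogates(bispecies):
    gA, gB, _ = bispecies
    return find_surrogate_repeats(gA, gB, min_len=50, min_identity=90.0, flank=80)


class TestSurrogateDiscovery:
    def test_all_four_planted_regions_recovered(self, bispecies, surrogates):
        """The four planted shared regions (55/90/148/639 nt) come back
        with correct lengths and coordinates."""
        _, _, truth = bispecies
        assert sorted(s.length for s in surrogates) == sorted(SHARED_LENGTHS)
        found = {(s.region_a.start, s.region_a.end) for s in surrogates}
        planted = {(iv.start, iv.end) for iv in truth.regions_a}
        assert found == planted

    def test_identities_match_planted(self, bispecies, surrogates):
        _, _, truth = bispecies
        by_coord = {(s.region_a.start, s.region_a.end): s for s in surrogates}
        for iv, ident in zip(truth.regions_a, truth.identities):
            assert by_coord[(iv.start, iv.end)].identity == pytest.approx(ident, abs=0.01)

    def test_single_planted_region(self):
        gA, gB, truth = generate_bispecies_fixture([148], [100.0], seed=3, L=8000)
        out = find_surrogate_repeats(gA, gB, min_len=50, min_identity=94.0, flank=80)
        assert len(out) == 1
        assert out[0].length == 148

    def test_region_with_shared_flank_excluded(self):
        """A shared region whose flank also occurs in the other genome
        fails the uniqueness requirement."""
        gA, gB, truth = generate_bispecies_fixture([148], [100.0], seed=5, L=8000)
        iv = truth.regions_a[0]
        flank_seq = gA.seq[iv.start - 81 : iv.start - 1]
        # graft A's upstream flank into B far from the shared region
        bseq = gB.seq
        pos = 100 if truth.regions_b[0].start > 1500 else 6000
        bseq = bseq[:pos] + flank_seq + bseq[pos + 80 :]
        gB2 = CircularGenome(id="speciesB", seq=bseq)
        out = find_surrogate_repeats(gA, gB2, min_len=50, min_identity=94.0, flank=80)
        assert out == []


class TestChimericProducts:
    def test_hand_concatenation_for_identical_region(self):
        gA, gB, truth = generate_bispecies_fixture([90], [100.0], seed=7, L=8000)
        (s,) = find_surrogate_repeats(gA, gB, min_len=50, min_identity=94.0, flank=80)
        ab, ba = expected_chimeric_products(s, gA, gB, flank=60)
        a, b = s.region_a, s.region_b
        up_a = gA.seq[a.start - 61 : a.start - 1]
        dn_a = gA.seq[a.end : a.end + 60]
        up_b = gB.seq[b.start - 61 : b.start - 1]
        dn_b = gB.seq[b.end : b.end + 60]
        rep = gA.seq[a.start - 1 : a.end]
        assert ab == up_a + rep + dn_b
        assert ba == up_b + rep + dn_a  # identical copies: same core

    def test_absent_from_both_genomes(self, bispecies, surrogates):
        gA, gB, _ = bispecies
        for s in surrogates:
            for chim in expected_chimeric_products(s, gA, gB, flank=60):
                for g in (gA, gB):
                    doubled = g.seq + g.seq
                    assert chim not in doubled
                    assert reverse_complement(chim) not in doubled

    def test_imperfect_region_variants_differ_only_inside_repeat(self, bispecies, surrogates):
        """For the 94%-identity region the two junction products differ
        from each other's haplotype only at the planted substitutions."""
        gA, gB, truth = bispecies
        idx = truth.lengths.index(148)
        region_a = truth.regions_a[idx]
        s148 = next(
            s for s in surrogates if (s.region_a.start, s.region_a.end) == (region_a.start, region_a.end)
        )
        ab, ba = expected_chimeric_products(s148, gA, gB, flank=60)
        rep_a = extract(gA, s148.region_a)
        rep_b = extract(gB, s148.region_b)
        diff_offsets = {i for i, (x, y) in enumerate(zip(rep_a, rep_b)) if x != y}
        planted_offsets = {
            p - truth.regions_b[idx].start for p in truth.mutated_positions_b[idx]
        }
        assert diff_offsets == planted_offsets
        # swap in the other haplotype: the chimera changes only inside the core
        alt_ab = ab[:60] + rep_b + ab[60 + 148 :]
        diffs = {i for i, (x, y) in enumerate(zip(ab, alt_ab)) if x != y}
        assert diffs == {o + 60 for o in planted_offsets}


def _assay(bispecies, surrogate, weight=2000.0, cycles=35):
    gA, gB, _ = bispecies
    pool = bispecies_pool(
        gA, gB, surrogate, flank=120, weight_a=weight, weight_b=weight, cycles=cycles
    )
    fwd = pool.templates[0].sequence[:20]
    rev = reverse_complement(pool.templates[1].sequence[-20:])
    return pool, (fwd, rev)


class TestSimulatePcr:
    def test_no_switching_no_chimeras(self, bispecies, surrogates):
        pool, primers = _assay(bispecies, surrogates[0])
        tally = simulate_pcr(pool, primers, p_switch=0.0, seed=1)
        assert tally.chimeric == 0
        assert tally.non_chimeric > 0

    def test_full_switching_all_informative_products_chimeric(self, bispecies, surrogates):
        pool, primers = _assay(bispecies, surrogates[0])
        tally = simulate_pcr(pool, primers, p_switch=1.0, seed=1)
        assert tally.informative > 0
        assert tally.informative_chimera_fraction == 1.0

    def test_reproducible_for_fixed_seed(self, bispecies, surrogates):
        pool, primers = _assay(bispecies, surrogates[0])
        a = simulate_pcr(pool, primers, p_switch=0.1, seed=42)
        b = simulate_pcr(pool, primers, p_switch=0.1, seed=42)
        assert (a.chimeric, a.non_chimeric) == (b.chimeric, b.non_chimeric)

    def test_single_species_pool_never_switches(self, bispecies, surrogates):
        gA, gB, _ = bispecies
        pool, primers = _assay(bispecies, surrogates[0])
        solo = PcrPool(templates=[pool.templates[0]], cycles=10)
        tally = simulate_pcr(solo, primers, p_switch=1.0, seed=2)
        assert tally.chimeric == 0

    def test_primer_matching_both_species_is_design_error(self, bispecies, surrogates):
        perfect = next(s for s in surrogates if s.identity == 100.0)
        pool, primers = _assay(bispecies, perfect)
        # the shared-region core itself occurs in both templates
        core20 = pool.templates[0].sequence[120:140]
        with pytest.raises(PrimerDesignError):
            simulate_pcr(pool, (core20, primers[1]), p_switch=0.1, seed=1)

    def test_matches_expectation_recursion(self, bispecies, surrogates):
        """Monte-Carlo chimera fraction agrees with the closed-form
        expectation recursion of the K=0 linear branching process."""
        pool, primers = _assay(bispecies, surrogates[0], weight=20_000.0, cycles=10)
        pool.half_saturation = 0.0
        pool.max_molecules = 10**15
        p_sw, e = 0.2, pool.efficiency
        # expectation recursion over types (left, right, strand)
        c = {(l, r, s): 0.0 for l in "AB" for r in "AB" for s in "+-"}
        c[("A", "A", "+")] = c[("A", "A", "-")] = 20_000.0
        c[("B", "B", "+")] = c[("B", "B", "-")] = 20_000.0
        exp_chim = exp_plain = 0.0
        for _ in range(pool.cycles):
            new = {k: 0.0 for k in c}
            for r in "AB":  # forward primer on '-' strands with left == A
                ev = e * c[("A", r, "-")]
                new[("A", "B", "+")] += ev * p_sw
                new[("A", r, "+")] += ev * (1 - p_sw)
            for l in "AB":  # reverse primer on '+' strands with right == B
                ev = e * c[(l, "B", "+")]
                new[("A", "B", "-")] += ev * p_sw
                new[(l, "B", "-")] += ev * (1 - p_sw)
            chim = sum(v for (l, r, s), v in new.items() if l != r)
            exp_chim += chim
            exp_plain += sum(new.values()) - chim
            for k in c:
                c[k] += new[k]
        expected_fraction = exp_chim / (exp_chim + exp_plain)
        tallies = [
            simulate_pcr(pool, primers, p_switch=p_sw, seed=s) for s in range(5)
        ]
        mc = np.mean([t.chimera_fraction for t in tallies])
        assert mc == pytest.approx(expected_fraction, rel=0.02)


class TestConcentrationResponse:
    def test_needs_two_dilutions(self, bispecies, surrogates):
        pool, primers = _assay(bispecies, surrogates[0])
        with pytest.raises(ValueError):
            concentration_response(pool, [1.0], primers, 0.1, seed=1)

    def test_seventyfold_contrast(self, bispecies, surrogates):
        """Amplicon-level template yields chimeras in (essentially) every
        assay; 70x-diluted total-DNA-level template in only a minority."""
        pool, primers = _assay(bispecies, surrogates[0])
        fr = concentration_response(
            pool, [1 / 70, 1.0], primers, p_switch=0.005, seed=3, replicates=40
        )
        low, high = fr.mean(axis=1)
        assert high > low
        assert (fr[1] > 0.5).mean() == 1.0  # all high-template assays positive
        assert (fr[0] > 0.5).mean() < 0.8  # a minority-to-some of low-template ones

    def test_identical_concentrations_indistinguishable(self, bispecies, surrogates):
        pool, primers = _assay(bispecies, surrogates[0])
        fr = concentration_response(
            pool, [1.0, 1.0], primers, p_switch=0.005, seed=4, replicates=30
        )
        # same input level: detection rates agree within binomial noise
        d = abs(fr[0].mean() - fr[1].mean())
        se = np.sqrt(fr.var(axis=1).sum() / 30)
        assert d <= 4 * max(se, 0.02)
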