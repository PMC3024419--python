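"""In-vitro (PCR-mediated) recombination: surrogate repeats and a
template-switching simulator.

Near-identical regions shared between two *different* genomes, each flanked
by sequence unique within and between the genomes, can serve as "surrogate
repeats": with one primer specific to each genome, no naturally occurring
template contains both primer sites, so any positive product must be a
chimera formed during PCR -- by polymerase template exchange across the
shared region, or by premature extension termination inside it followed by
re-priming on the other genome's homologue.

The simulator models that mechanism as a strand-aware branching process.
Each cycle, every primeable single strand is extended with efficiency
``e``; an extension crossing the shared region switches to a homologous
template of the other species with probability::

    p_eff = p_switch * c / (c + K)

where ``c`` is the current count of partner templates and ``K`` a
half-saturation constant (so switching needs a partner to re-anneal to, and
is more frequent at higher template concentration; ``K = 0`` gives a
constant-probability process with closed-form expectations).  Strandedness
is tracked: a product carrying only one primer site amplifies linearly, a
chimeric product carrying both amplifies exponentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circgenome import CircInterval, CircularGenome, extract, reverse_complement
from .repeat_finder import AlignmentParams, RepeatHit, _hit_from_raw, _kmer_index, _scan_seeds

__all__ = [
    "SurrogateRepeat",
    "PcrTemplate",
    "PcrPool",
    "ProductTally",
    "PrimerDesignError",
    "find_surrogate_repeats",
    "expected_chimeric_products",
    "bispecies_pool",
    "simulate_pcr",
    "concentration_response",
]


class PrimerDesignError(ValueError):
    """A primer matches templates of both species (or of neither)."""


@dataclass(frozen=True)
class SurrogateRepeat:
    """A near-identical region shared between two genomes.

    ``region_a``/``region_b`` are the homologous intervals (region_b on '-'
    when the similarity is to the reverse complement).  ``flanks_a`` and
    ``flanks_b`` are the unique upstream/downstream flank intervals used by
    the assays.
    """

    region_a: CircInterval
    region_b: CircInterval
    length: int
    identity: float
    flanks_a: tuple[CircInterval, CircInterval]
    flanks_b: tuple[CircInterval, CircInterval]


def _cross_alignments(
    gA: CircularGenome, gB: CircularGenome, p: AlignmentParams
) -> list[RepeatHit]:
    """Local alignments between two genomes (both orientations)."""
    idxA = _kmer_index(gA.seq, p.word_size)
    idxB = _kmer_index(gB.seq, p.word_size)
    direct_seeds = [
        (i, j) for k, pis in idxA.items() if k in idxB for i in pis for j in idxB[k]
    ]
    rcB = reverse_complement(gB.seq)
    idxBr = _kmer_index(rcB, p.word_size)
    inv_seeds = [
        (i, j) for k, pis in idxA.items() if k in idxBr for i in pis for j in idxBr[k]
    ]
    hits = []
    for aln in _scan_seeds(gA.seq, gB.seq, direct_seeds, p):
        hits.append(_hit_from_raw(aln, "direct", gB.length, gA.length, p, cross=True))
    for aln in _scan_seeds(gA.seq, rcB, inv_seeds, p):
        hits.append(_hit_from_raw(aln, "inverted", gB.length, gA.length, p, cross=True))
    return hits


def _unique_within(g: CircularGenome, oligo: str) -> bool:
    hay = g.seq + (g.seq[: len(oligo) - 1] if g.circular else "")
    n = hay.count(oligo) + hay.count(reverse_complement(oligo))
    return n == 1


def _absent_from(g: CircularGenome, oligo: str) -> bool:
    hay = g.seq + (g.seq[: len(oligo) - 1] if g.circular else "")
    return oligo not in hay and reverse_complement(oligo) not in hay


def find_surrogate_repeats(
    gA: CircularGenome,
    gB: CircularGenome,
    min_len: int = 50,
    min_identity: float = 94.0,
    flank: int = 100,
    params: AlignmentParams | None = None,
) -> list[SurrogateRepeat]:
    """Cross-genome shared regions with unique flanks in both genomes.

    Uses the same seed-and-extend engine as the repeat search.  A region
    qualifies when its alignment is at least ``min_len`` long at
    ``min_identity`` percent, and the ``flank`` nt on each side occur
    exactly once within their own genome and nowhere in the other genome.
    """
    p = params or AlignmentParams()
    out = []
    for h in _cross_alignments(gA, gB, p):
        if (h.aln_length or 0) < min_len or h.identity < min_identity:
            continue
        if h.evalue > p.e_cutoff:
            continue
        a, b = h.copy1, h.copy2
        La, Lb = gA.length, gB.length
        up_a = CircInterval(start=(a.start - 1 - flank) % La + 1, end=(a.start - 2) % La + 1)
        dn_a = CircInterval(start=a.end % La + 1, end=(a.end + flank - 1) % La + 1)
        if b.strand == "+":
            up_b = CircInterval(start=(b.start - 1 - flank) % Lb + 1, end=(b.start - 2) % Lb + 1)
            dn_b = CircInterval(start=b.end % Lb + 1, end=(b.end + flank - 1) % Lb + 1)
        else:
            up_b = CircInterval(start=b.end % Lb + 1, end=(b.end + flank - 1) % Lb + 1, strand="-")
            dn_b = CircInterval(start=(b.start - 1 - flank) % Lb + 1, end=(b.start - 2) % Lb + 1, strand="-")
        flank_seqs_a = [extract(gA, up_a), extract(gA, dn_a)]
        flank_seqs_b = [extract(gB, up_b), extract(gB, dn_b)]
        ok = all(_unique_within(gA, s) and _absent_from(gB, s) for s in flank_seqs_a)
        ok = ok and all(
            _unique_within(gB, s) and _absent_from(gA, s) for s in flank_seqs_b
        )
        if not ok:
            continue
        out.append(
            SurrogateRepeat(
                region_a=a,
                region_b=b,
                length=h.aln_length or a.length(La),
                identity=h.identity,
                flanks_a=(up_a, dn_a),
                flanks_b=(up_b, dn_b),
            )
        )
    out.sort(key=lambda s: s.region_a.start)
    return out


def expected_chimeric_products(
    s: SurrogateRepeat, gA: CircularGenome, gB: CircularGenome, flank: int
) -> tuple[str, str]:
    """The two predicted cross-species junction sequences.

    ``A->B``: A's upstream flank + the shared region (A's variant) + B's
    downstream flank; ``B->A`` is the reciprocal with B's variant.  Both
    strings are absent from both genomes whenever the flanks are unique.
    """
    La, Lb = gA.length, gB.length
    a, b = s.region_a, s.region_b
    if flank < 1:
        raise ValueError("flank must be >= 1")

    def civ(start, end, L, strand="+"):
        return CircInterval(start=(start - 1) % L + 1, end=(end - 1) % L + 1, strand=strand)

    up_a = extract(gA, civ(a.start - flank, a.start - 1, La))
    dn_a = extract(gA, civ(a.end + 1, a.end + flank, La))
    rep_a = extract(gA, a)
    rep_b = extract(gB, b)  # strand-aware: read in alignment orientation
    if b.strand == "+":
        up_b = extract(gB, civ(b.start - flank, b.start - 1, Lb))
        dn_b = extract(gB, civ(b.end + 1, b.end + flank, Lb))
    else:
        up_b = extract(gB, civ(b.end + 1, b.end + flank, Lb, "-"))
        dn_b = extract(gB, civ(b.start - flank, b.start - 1, Lb, "-"))
    return up_a + rep_a + dn_b, up_b + rep_b + dn_a


# ---------------------------------------------------------------------------
# template-switching simulator


@dataclass(frozen=True)
class PcrTemplate:
    species: str
    sequence: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("concentration weight must be positive")


@dataclass
class PcrPool:
    templates: list[PcrTemplate]
    cycles: int = 35
    efficiency: float = 0.9
    half_saturation: float = 500.0
    max_molecules: int = 10**7

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycle count must be >= 1")

    def species(self) -> list[str]:
        seen = []
        for t in self.templates:
            if t.species not in seen:
                seen.append(t.species)
        return seen

    def diluted(self, factor: float) -> "PcrPool":
        return PcrPool(
            templates=[
                PcrTemplate(t.species, t.sequence, t.weight * factor)
                for t in self.templates
            ],
            cycles=self.cycles,
            efficiency=self.efficiency,
            half_saturation=self.half_saturation,
            max_molecules=self.max_molecules,
        )


def bispecies_pool(
    gA: CircularGenome,
    gB: CircularGenome,
    s: SurrogateRepeat,
    flank: int,
    weight_a: float,
    weight_b: float,
    cycles: int = 35,
    **kwargs,
) -> PcrPool:
    """Amplicon-style two-template pool around one surrogate repeat."""
    La, Lb = gA.length, gB.length

    def civ(start, end, L, strand="+"):
        return CircInterval(start=(start - 1) % L + 1, end=(end - 1) % L + 1, strand=strand)

    a, b = s.region_a, s.region_b
    seq_a = extract(gA, civ(a.start - flank, a.end + flank, La))
    if b.strand == "+":
        seq_b = extract(gB, civ(b.start - flank, b.end + flank, Lb))
    else:
        seq_b = extract(gB, civ(b.start - flank, b.end + flank, Lb, "-"))
    return PcrPool(
        templates=[
            PcrTemplate(gA.id, seq_a, weight_a),
            PcrTemplate(gB.id, seq_b, weight_b),
        ],
        cycles=cycles,
        **kwargs,
    )


@dataclass
class ProductTally:
    non_chimeric: int
    chimeric: int
    cycles: int
    informative: int = 0  # synthesized strands carrying both primer sites
    by_type: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.non_chimeric + self.chimeric

    @property
    def chimera_fraction(self) -> float:
        return self.chimeric / self.total if self.total else 0.0

    @property
    def informative_chimera_fraction(self) -> float:
        """Chimeric share of products amplifiable by the bi-species pair.

        With species-specific primers no natural template carries both
        sites, so this is 1 whenever any informative product exists.
        """
        return self.chimeric / self.informative if self.informative else 0.0

    def detected(self, threshold: int = 1) -> bool:
        """Gel-band semantics: a product count at/above threshold shows."""
        return self.chimeric >= threshold


def _primer_species(primer: str, pool: PcrPool) -> str | None:
    """Species whose templates carry the primer site; None if absent.

    A primer binding templates of more than one species cannot give a
    species-specific assay and is a design error.
    """
    matches = set()
    for t in pool.templates:
        if primer in t.sequence or reverse_complement(primer) in t.sequence:
            matches.add(t.species)
    if len(matches) > 1:
        raise PrimerDesignError(f"primer matches both species: {sorted(matches)}")
    return matches.pop() if matches else None


def simulate_pcr(
    pool: PcrPool,
    primers: tuple[str, str],
    p_switch: float,
    seed: int,
) -> ProductTally:
    """Simulate ``pool.cycles`` cycles of PCR with a bi-species primer pair.

    The forward primer must be specific to one species' flank and the
    reverse primer to the other's.  Returns the tally of synthesized
    full-length strands, chimeric (mixed-species) and not.  Seeded and
    reproducible.
    """
    if not 0.0 <= p_switch <= 1.0:
        raise ValueError("p_switch must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fwd, rev = primers
    sp_f = _primer_species(fwd, pool)
    sp_r = _primer_species(rev, pool)
    if sp_f is None and sp_r is None:
        raise PrimerDesignError("neither primer matches any template")
    species = pool.species()
    if sp_f is None:
        sp_f = next((s for s in species if s != sp_r), sp_r)
    if sp_r is None:
        sp_r = next((s for s in species if s != sp_f), sp_f)
    # index 0 = forward-primer species (left flank), 1 = reverse-primer species
    def side(sp: str) -> int:
        return 0 if sp == sp_f else 1

    # counts[left, right, strand]; strand 0 = '+' (primeable by reverse
    # primer when right flank matches), 1 = '-' (primeable by forward
    # primer when left flank matches)
    counts = np.zeros((2, 2, 2), dtype=np.int64)
    for t in pool.templates:
        s = side(t.species)
        w = int(round(t.weight))
        counts[s, s, 0] += w
        counts[s, s, 1] += w
    e = pool.efficiency
    K = pool.half_saturation
    # Switch propensity scales with the *input* template concentration of
    # the partner species (the experimentally varied covariate): a nascent
    # strand that stalls in the shared region finds a partner to re-anneal
    # to at a rate saturating in partner input.  K = 0 makes the propensity
    # a flat p_switch, giving a linear branching process with closed-form
    # expectations.
    c_right1 = int(counts[:, 1, :].sum())  # input templates with sp_r right half
    c_left0 = int(counts[0, :, :].sum())  # input templates with sp_f left half
    if K == 0:
        p_f = p_switch if c_right1 > 0 else 0.0
        p_r = p_switch if c_left0 > 0 else 0.0
    else:
        p_f = p_switch * (c_right1 / (c_right1 + K)) if c_right1 > 0 else 0.0
        p_r = p_switch * (c_left0 / (c_left0 + K)) if c_left0 > 0 else 0.0
    synth_chim = 0
    synth_plain = 0
    for _ in range(pool.cycles):
        new = np.zeros_like(counts)
        # forward primer on '-' strands with sp_f left flank
        for r in (0, 1):
            n = int(counts[0, r, 1])
            if n == 0:
                continue
            ev = rng.binomial(n, e)
            sw = rng.binomial(ev, p_f) if ev else 0
            new[0, 1, 0] += sw
            new[0, r, 0] += ev - sw
        # reverse primer on '+' strands with sp_r right flank
        for l in (0, 1):
            n = int(counts[l, 1, 0])
            if n == 0:
                continue
            ev = rng.binomial(n, e)
            sw = rng.binomial(ev, p_r) if ev else 0
            new[0, 1, 1] += sw
            new[l, 1, 1] += ev - sw
        chim = int(new[0, 1, :].sum() + new[1, 0, :].sum())
        synth_chim += chim
        synth_plain += int(new.sum()) - chim
        counts += new
        total = int(counts.sum())
        if total > pool.max_molecules:
            # dilute the tube, preserving composition
            frac = pool.max_molecules / total
            flat = counts.reshape(-1)
            counts = rng.binomial(flat, frac).reshape(counts.shape).astype(np.int64)
    by_type = {
        (l, r, s): int(counts[li, ri, si])
        for li, l in enumerate((sp_f, sp_r))
        for ri, r in enumerate((sp_f, sp_r))
        for si, s in enumerate("+-")
    }
    return ProductTally(
        non_chimeric=synth_plain,
        chimeric=synth_chim,
        cycles=pool.cycles,
        informative=synth_chim,  # only mixed-species strands carry both sites
        by_type=by_type,
    )


def concentration_response(
    pool: PcrPool,
    dilutions: Sequence[float],
    primers: tuple[str, str],
    p_switch: float,
    seed: int,
    replicates: int = 1,
) -> np.ndarray:
    """Chimera fraction per dilution level.

    Returns an array of shape ``(len(dilutions), replicates)``; dilution
    factors multiply every template weight.  In expectation the chimera
    fraction is non-decreasing in template concentration.
    """
    if len(dilutions) < 2:
        raise ValueError("need at least two dilution levels")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(dilutions) * replicates)
    out = np.zeros((len(dilutions), replicates))
    k = 0
    for i, f in enumerate(dilutions):
        for j in range(replicates):
            tally = simulate_pcr(pool.diluted(f), primers, p_switch, int(seeds[k] % (2**31)))
            out[i, j] = tally.chimera_fraction
            k += 1
    return out
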