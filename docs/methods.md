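# Methods

This note documents the models implemented in `mito-recomb`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real data.

## Coordinates and topology

All public interfaces use 1-based inclusive coordinates, the convention of
GenBank records and published organelle repeat tables; conversion to
0-based half-open happens only inside the BED writer. A circular genome of
length L treats position L as adjacent to position 1, and an interval with
`start > end` wraps through the origin — the single encoding used for
origin-spanning features. Sequences are normalised to upper case over
{A, C, G, T, N}; N is excluded from both numerator and denominator of GC
content.

## Repeat discovery

`repeat_finder` aligns the genome against itself, forward–forward and
forward–reverse-complement.

*Seeding.* All exact shared words of length `word_size` (default W = 7)
are enumerated from a k-mer index; ordered pairs (i < j) make mirror
duplicates impossible, and a position is never paired with itself on the
same strand. Seeds are grouped by diagonal (antidiagonal for inverted
matches) and a seed inside a region already aligned on its diagonal is
skipped.

*Extension.* From each seed the alignment is extended in both directions
under match/mismatch scores M = +1, N = −3 with X-drop termination
(default X = 20 score units: extension stops once the running score falls
X below the best prefix, and the best-scoring endpoint is kept). At each
stall a greedy gap-crossing step tries resuming on a diagonal shifted by
up to `max_gap` positions, charging `gap_open + gap_extend·d` (defaults
Q = 3, R = 3) and accepting the shift only if the resumed extension more
than pays for it. This is a heuristic stand-in for a full gapped X-drop
dynamic program: for substitution-diverged repeats (the relevant regime —
published organelle repeat copies are equal-length) it returns the maximal
gapless alignment exactly, and it crosses isolated short indels, but it is
not guaranteed to find the optimal alignment through complex gap
structure. In direct self-comparison, gap crossings may not land on the
identity diagonal, which would otherwise extend along the trivial
self-match.

*Statistics.* Each alignment of score S is assigned the Karlin–Altschul
expectation E = K·m·n·e^(−λS) with m = n = L. The paper trail for this
scoring scheme names the scores but not the statistical parameters; the
defaults λ = 1.374 nats and K = 0.711 are the standard ungapped values for
+1/−3 scoring, and both are exposed in `AlignmentParams`. Hits with
E ≤ `e_cutoff` (default 1.0) are repeats. Note the practical consequence:
by construction, a random genome yields on the order of one chance hit per
self-search at E ≤ 1, so hit lists on real or synthetic genomes may
contain a few short low-scoring entries beyond the planted/biological
repeats.

*Circularity.* The search runs on the genome as given and again rotated by
L/2; coordinates are mapped back, exact duplicates are merged, and a hit
whose two copies are both contained in another hit's copies (a truncated
rotation artefact) is dropped in favour of the higher-scoring version.

## Repeat statistics

Coverage is per-position and non-redundant: a position covered by several
repeat copies counts once. A hit belongs to the short (< 1 kb) or large
(≥ 1 kb) class by its own alignment length; a *position* covered by one
hit of each class forms the short-within-large class, so the four classes
(including non-repetitive) partition the genome exactly — an invariant
enforced by the profile dataclass itself.

Repeat number follows the unique begin–end coordinate convention: the
count of distinct (start, end) pairs over all hit copies. For a k-copy
family this ranges from k (perfect family) to k(k−1) (imperfect, variably
sized copies), derived by enumerating copy pairs rather than transcribing
a formula. A caution established while testing: with a 4-letter alphabet,
any perfect family of ≥ 5 copies has some pair whose adjacent flanking
bases agree by chance, so a maximal local alignment necessarily overruns
the core for that pair and the coordinate count exceeds k even for perfect
copies. Coordinate counts systematically over-estimate family sizes; the
end-to-end identity `count = k` is only demonstrable for k ≤ 4 with
delimiter-sharpened fixtures.

## Recombination geometry

For a direct repeat with copy starts s₁ < s₂ on a circle of length L, a
single crossover yields two circles of sizes s₂−s₁ and L−(s₂−s₁) (they sum
to L exactly); each retains one repeat copy joined to the *other* copy's
former flank. For an inverted repeat the product is one circle of
unchanged size with the segment strictly between the copies
reverse-complemented; applying the operation twice restores the reference.
Junction sequences are flank + retained copy + flank; when the copies
differ, the copy physically retained at each junction supplies the
variant sites, and because real recombinants may carry gene-conversion
tracts mixing the two haplotypes, the retained-copy interval is surfaced
as metadata rather than asserted as the only possible product. Junctions
are absent from the reference genome whenever the flanks are unique —
which is exactly why junction-spanning reads and junction-specific PCR
are informative.

Assay layout slides a `primer_len` window (default 20 nt) outward from
each repeat boundary until the window sequence occurs exactly once in the
genome (both strands, circularly); failure to find a unique window within
the `max_product` budget is reported, not fatal. The expected recombinant
product size and any product the pair would also form on the reference are
computed from primer-site occurrences and orientations.

Chimeric-read detection first discards any read that matches the
reference circle on either strand (exactly, or within `max_mismatch`
edits via edlib infix alignment), then matches the remainder against the
predicted junction sequences, requiring at least `min_anchor` nt
(default 20) of match in the unique flank on *both* sides of the repeat
copy — anchors inside the repeat cannot tell the copies apart. Reference
support for the ratio estimate is the symmetric quantity: reads matching
the reference that span a repeat copy plus `min_anchor` on both sides.
The reference:recombinant ratio is reported per repeat and flagged
undefined when no recombinant reads exist.

## PCR-mediated recombination

Surrogate repeats are near-identical regions shared between two different
genomes (same alignment engine, cross-genome), kept only when `flank` nt
on each side occur exactly once within their own genome and nowhere in
the other. With one primer specific to each genome, no natural template
carries both sites, so any positive product must have formed in vitro.

The simulator is a strand-aware branching process over product types
(left-half species, right-half species, strand). Each cycle every
primeable single strand is copied with efficiency `e` (default 0.9); an
extension crossing the shared region switches to the homologous template
of the other species with probability

    p_eff = p_switch · c₀ / (c₀ + K)

where c₀ is the *input* template count of the partner species and K a
half-saturation constant (default 500 molecules in the pool's arbitrary
units). Strandedness makes single-primer products amplify linearly and
chimeric products (both primer sites) exponentially — the mechanism by
which a single early switching event produces a dominant chimeric band.
Pinning the switch propensity to the input concentration (rather than the
growing product pool) is a deliberate simplification: feeding the product
pool back saturates the chimera fraction at ~1 for any input after 35
cycles and erases the concentration dependence observed experimentally;
with the input-pinned propensity the simulator reproduces it — at
amplicon-level template every seeded assay yields chimeric product, at
~70-fold lower (total-DNA-like) template only a minority do. With K = 0
the propensity is a flat `p_switch` and the process is a linear branching
process whose expectation recursion is closed-form; the test suite checks
the Monte-Carlo simulator against that recursion. A `p_switch` of roughly
0.002–0.01 per crossing reproduces the observed minority-of-assays
behaviour at low template; the simulator makes no attempt to predict
*which* assays succeed, only the concentration trend. The polymerase is
error-free: the evidence this models concerns junction identity, not
point errors.

## Partition accounting

Every position is assigned to exactly one top-level category by a
precedence order (default: conserved syntenic > chloroplast-like >
nuclear-like > mitochondrial-like; positions in no category are
uncharacterized), so counts always sum to L — enforced at construction.
The order between chloroplast- and nuclear-like is not derivable from the
published table and is config-exposed. Sub-features (protein exons,
cis-spliced introns, rRNA, tRNA) are reported informationally and take no
part in the exactness invariant. Percentages print to one decimal;
round-half-up is the default (matching the published style) with banker's
rounding available.

## Synthetic data

The generator emulates the study conditions: i.i.d. background sequence at
45.1 % GC; planted repeat pairs spanning the studied ranges (lengths
38–1362 nt, identities 93–100 %, both orientations); recombinant molecule
pools at 40–100× under-abundance; error-free shotgun reads with uniform
circular starts, molecules drawn proportionally to weight × length, and an
expected count of `depth · L_reference / read_len`.

Two deliberate constructions make "exact boundary recovery" well defined.
Substitutions realising a target identity are placed ≥ 4 nt from the copy
ends *and* ≥ 4 nt apart, so under +1/−3 scoring every alignment prefix and
suffix has positive score and the planted span is the unique maximal local
alignment (clustered end-proximal substitutions would otherwise cause
legitimate boundary trimming). Second, the three alignment-facing flank
bases on each side of a planted pair are forced to mismatch; a single
chance flank match would extend the optimal alignment one base past the
plant roughly a quarter of the time. Real repeat boundaries are themselves
alignment-defined, so these constraints encode sharp boundaries rather
than hiding a defect.

What passing tests therefore show: the pipeline recovers alignment-sharp,
substitution-diverged repeats exactly, obeys the conservation laws of
single-crossover recombination, and classifies error-free reads with
perfect precision and recall. What they do not show: behaviour on
gap-diverged or tandem-degenerate repeat families, on reads with realistic
error profiles (an optional uniform substitution rate exists but Sanger
error structure is not modelled), on genomes with composition bias or
repeat-dense backgrounds, or exact reproduction of WU-BLAST hit lists
(hit-culling heuristics of that engine are not replicated).

## Problem sizes and numerics

Test fixtures use 6–20 kb genomes (0.4 Mb only for coordinate-arithmetic
checks), chosen so the full suite runs in well under a minute while
exercising every code path at the study's repeat dimensions; all
simulations are seeded through `numpy.random.default_rng` and
reproducible. Ties in the greedy gap-crossing step resolve toward the
highest net score (first-found on equality); degenerate inputs (empty hit
lists, zero-depth read pools, single-template PCR pools) return empty or
zero-valued results rather than errors, except where a precondition is
violated (overlapping repeat copies, flanks overrunning the partner copy,
primers matching both species), which raise typed exceptions.
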