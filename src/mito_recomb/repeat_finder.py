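"""Dispersed-repeat discovery by seed-and-extend self-alignment.

The genome is compared against itself (forward-forward and
forward-reverse-complement) with an exact word seed, ungapped X-drop
extension under a +M/-N substitution score with a greedy gap-crossing step
(gap of d positions costs Q + R*d), and Karlin-Altschul E-value filtering
E = K*m*n*exp(-lambda*S).  Hits with E <= e_cutoff are reported as repeats.

Defaults follow the WU-BLAST style settings used for plant mitochondrial
repeat surveys: W=7, M=+1, N=-3, Q=3, R=3, E-cutoff 1.  The statistical
parameters lambda and K are the standard ungapped values for +1/-3 scoring
(lambda ~ 1.374 nats, K ~ 0.711) and are exposed in
:class:`AlignmentParams`.

Circularity is handled by repeating the search on the genome rotated by
L/2 and deduplicating, so repeats spanning the origin are found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .circgenome import CircInterval, CircularGenome, reverse_complement

__all__ = [
    "AlignmentParams",
    "RepeatHit",
    "seed_matches",
    "extend_hit",
    "evalue",
    "filter_and_canonicalize",
    "find_repeats",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and filtering parameters for the self-alignment search.

    word_size
        Exact-match seed length W (>= 4).
    match, mismatch
        Substitution scores M (> 0) and N (< 0).
    gap_open, gap_extend
        A gap of d positions costs ``gap_open + gap_extend * d``.
    lam, k
        Karlin-Altschul lambda (nats per score unit) and K.
    e_cutoff
        Hits with E-value above this are discarded.
    x_drop
        Extension stops once the running score falls this far below the
        best score seen (score units).
    max_gap
        Largest single gap the greedy gap-crossing step will attempt.
    """

    word_size: int = 7
    match: int = 1
    mismatch: int = -3
    gap_open: int = 3
    gap_extend: int = 3
    lam: float = 1.374
    k: float = 0.711
    e_cutoff: float = 1.0
    x_drop: int = 20
    max_gap: int = 3

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")


@dataclass(frozen=True)
class RepeatHit:
    """A pair of aligned repeat copies.

    For direct hits both copies are on '+'; for inverted hits copy2 carries
    the '-' strand (its sequence reverse-complement-matches copy1).
    Canonical ordering puts the copy with the smaller start first.
    """

    copy1: CircInterval
    copy2: CircInterval
    orientation: str  # "direct" | "inverted"
    score: float
    evalue: float
    identity: float
    aln_length: int | None = None
    cross_genome: bool = False  # copy2 lives on a different genome

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not self.cross_genome and (
            self.copy1.start,
            self.copy1.end,
            self.copy1.strand,
        ) == (self.copy2.start, self.copy2.end, self.copy2.strand):
            raise ValueError("copy1 and copy2 must differ")
        if not (0.0 < self.identity <= 100.0):
            raise ValueError("identity must be in (0, 100]")


def evalue(score: float, m: int, n: int, p: AlignmentParams) -> float:
    """Karlin-Altschul expectation: E = K * m * n * exp(-lambda * score)."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space sizes m and n must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    return p.k * m * n * math.exp(-p.lam * score)


# ---------------------------------------------------------------------------
# seeding


def _kmer_index(seq: str, W: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - W + 1):
        index.setdefault(seq[i : i + W], []).append(i)
    return index


def seed_matches(g: CircularGenome, W: int) -> list[tuple[int, int, str]]:
    """All exact W-mer matches of the genome against itself.

    Returns 1-based ``(start1, start2, orientation)`` triples with
    ``start1 < start2`` (which removes mirror duplicates) and never pairs a
    position with itself on the same strand.  Both forward-forward
    ("direct") and forward-reverse-complement ("inverted") words are
    reported.  Does not consider origin-spanning words; the full search in
    :func:`find_repeats` recovers those by rotation.
    """
    if g.length < W:
        raise ValueError(f"genome shorter than word size {W}")
    seq = g.seq
    fwd = _kmer_index(seq, W)
    out: list[tuple[int, int, str]] = []
    for positions in fwd.values():
        if len(positions) > 1:
            for a in range(len(positions)):
                for b in range(a + 1, len(positions)):
                    out.append((positions[a] + 1, positions[b] + 1, "direct"))
    seen = set()
    for kmer, positions in fwd.items():
        rc = reverse_complement(kmer)
        if rc not in fwd or kmer in seen:
            continue
        seen.add(kmer)
        seen.add(rc)
        if rc == kmer:  # palindromic word: pair distinct positions once
            for a in range(len(positions)):
                for b in range(a + 1, len(positions)):
                    out.append((positions[a] + 1, positions[b] + 1, "inverted"))
        else:
            for i in positions:
                for j in fwd[rc]:
                    if i < j:
                        out.append((i + 1, j + 1, "inverted"))
                    elif j < i:
                        out.append((j + 1, i + 1, "inverted"))
    return out


# ---------------------------------------------------------------------------
# extension


def _ext_forward(s1: str, s2: str, i: int, j: int, M: int, mm: int, X: int):
    """Ungapped extension to the right starting at s1[i], s2[j].

    Returns (best_gain, best_cols, best_matches, stopped_at_end).
    """
    n1, n2 = len(s1), len(s2)
    cur = 0
    best = 0
    best_cols = 0
    best_matches = 0
    matches = 0
    t = 0
    while i + t < n1 and j + t < n2:
        cur += M if s1[i + t] == s2[j + t] else mm
        if s1[i + t] == s2[j + t]:
            matches += 1
        t += 1
        if cur > best:
            best, best_cols, best_matches = cur, t, matches
        elif cur < best - X:
            return best, best_cols, best_matches, False
    return best, best_cols, best_matches, True


def _ext_backward(s1: str, s2: str, i: int, j: int, M: int, mm: int, X: int):
    """Ungapped extension to the left ending just before s1[i+1], s2[j+1].

    ``i`` and ``j`` are the first candidate positions (inclusive), moving
    toward 0.  Same return convention as :func:`_ext_forward`.
    """
    cur = 0
    best = 0
    best_cols = 0
    best_matches = 0
    matches = 0
    t = 0
    while i - t >= 0 and j - t >= 0:
        cur += M if s1[i - t] == s2[j - t] else mm
        if s1[i - t] == s2[j - t]:
            matches += 1
        t += 1
        if cur > best:
            best, best_cols, best_matches = cur, t, matches
        elif cur < best - X:
            return best, best_cols, best_matches, False
    return best, best_cols, best_matches, True


@dataclass
class _RawAln:
    """0-based inclusive alignment coordinates on two working strings."""

    i1: int
    e1: int
    i2: int
    e2: int
    score: int
    matches: int
    cols: int


def _extend_seed(
    s1: str, s2: str, i0: int, j0: int, p: AlignmentParams, self_mode: bool = False
) -> _RawAln:
    """Seed at s1[i0:i0+W] == s2[j0:j0+W]; extend both ways, greedy gaps.

    In ``self_mode`` (direct self-comparison) gap crossings may not land on
    the identity diagonal, which would extend along the trivial self-match.
    """
    M, mm, X, W = p.match, p.mismatch, p.x_drop, p.word_size
    score = W * M
    matches = W
    cols = W
    # right
    e1, e2 = i0 + W - 1, j0 + W - 1
    for _ in range(16):
        gain, c, mt, at_end = _ext_forward(s1, s2, e1 + 1, e2 + 1, M, mm, X)
        score += gain
        matches += mt
        cols += c
        e1 += c
        e2 += c
        if at_end:
            break
        # greedy gap crossing: try resuming on a shifted diagonal
        best = None
        for d in range(1, p.max_gap + 1):
            for di, dj in ((d, 0), (0, d)):
                if self_mode and (e2 + dj) - (e1 + di) == 0:
                    continue
                g2, c2, mt2, _ = _ext_forward(
                    s1, s2, e1 + 1 + di, e2 + 1 + dj, M, mm, X
                )
                net = g2 - (p.gap_open + p.gap_extend * d)
                if net > 0 and (best is None or net > best[0]):
                    best = (net, d, di, dj, g2, c2, mt2)
        if best is None:
            break
        net, d, di, dj, g2, c2, mt2 = best
        score += net
        matches += mt2
        cols += d + c2
        e1 += di + c2
        e2 += dj + c2
    # left
    b1, b2 = i0, j0
    for _ in range(16):
        gain, c, mt, at_end = _ext_backward(s1, s2, b1 - 1, b2 - 1, M, mm, X)
        score += gain
        matches += mt
        cols += c
        b1 -= c
        b2 -= c
        if at_end:
            break
        best = None
        for d in range(1, p.max_gap + 1):
            for di, dj in ((d, 0), (0, d)):
                if self_mode and (b2 - dj) - (b1 - di) == 0:
                    continue
                g2, c2, mt2, _ = _ext_backward(
                    s1, s2, b1 - 1 - di, b2 - 1 - dj, M, mm, X
                )
                net = g2 - (p.gap_open + p.gap_extend * d)
                if net > 0 and (best is None or net > best[0]):
                    best = (net, d, di, dj, g2, c2, mt2)
        if best is None:
            break
        net, d, di, dj, g2, c2, mt2 = best
        score += net
        matches += mt2
        cols += d + c2
        b1 -= di + c2
        b2 -= dj + c2
    return _RawAln(i1=b1, e1=e1, i2=b2, e2=e2, score=score, matches=matches, cols=cols)


def _scan_seeds(
    s1: str,
    s2: str,
    seeds: list[tuple[int, int]],
    p: AlignmentParams,
    self_mode: bool = False,
) -> list[_RawAln]:
    """Extend seeds grouped by diagonal, skipping seeds inside a region
    already covered by an accepted alignment on the same diagonal."""
    seeds = sorted(seeds, key=lambda ij: (ij[1] - ij[0], ij[0]))
    covered_end: dict[int, int] = {}
    out = []
    W = p.word_size
    for i, j in seeds:
        diag = j - i
        if covered_end.get(diag, -1) >= i + W - 1:
            continue
        aln = _extend_seed(s1, s2, i, j, p, self_mode=self_mode)
        covered_end[diag] = max(covered_end.get(diag, -1), aln.e1)
        out.append(aln)
    return out


def extend_hit(
    g: CircularGenome, seed: tuple[int, int, str], p: AlignmentParams | None = None
) -> RepeatHit:
    """Extend a single seed triple (1-based start1, start2, orientation)."""
    p = p or AlignmentParams()
    s1, s2, orientation = seed[0] - 1, seed[1] - 1, seed[2]
    if orientation == "direct":
        aln = _extend_seed(g.seq, g.seq, s1, s2, p)
        return _hit_from_raw(aln, "direct", g.length, g.length, p)
    rc = reverse_complement(g.seq)
    j0 = g.length - p.word_size - s2  # transformed coordinate in rc space
    aln = _extend_seed(g.seq, rc, s1, j0, p)
    return _hit_from_raw(aln, "inverted", g.length, g.length, p)


def _hit_from_raw(
    aln: _RawAln,
    orientation: str,
    L2: int,
    L: int,
    p: AlignmentParams,
    cross: bool = False,
) -> RepeatHit:
    """Convert working-string coordinates to genome coordinates.

    For inverted hits the second string is the reverse complement of a
    sequence of length ``L2``; its coordinates are mapped back.
    """
    c1 = CircInterval(start=aln.i1 + 1, end=aln.e1 + 1, strand="+")
    if orientation == "direct":
        c2 = CircInterval(start=aln.i2 + 1, end=aln.e2 + 1, strand="+")
    else:
        c2 = CircInterval(start=L2 - aln.e2, end=L2 - aln.i2, strand="-")
    ident = 100.0 * aln.matches / aln.cols
    ev = evalue(max(aln.score, 0), L, L2, p)
    return RepeatHit(
        copy1=c1,
        copy2=c2,
        orientation=orientation,
        score=aln.score,
        evalue=ev,
        identity=ident,
        aln_length=aln.cols,
        cross_genome=cross,
    )


# ---------------------------------------------------------------------------
# full search


def _self_search(seq: str, p: AlignmentParams) -> list[_RawAln | tuple]:
    """Raw direct and inverted alignments of ``seq`` against itself."""
    W = p.word_size
    fwd = _kmer_index(seq, W)
    direct_seeds = []
    for positions in fwd.values():
        if len(positions) > 1:
            for a in range(len(positions)):
                for b in range(a + 1, len(positions)):
                    direct_seeds.append((positions[a], positions[b]))
    L = len(seq)
    rcseq = reverse_complement(seq)
    inv_seeds = []
    seen_words = set()
    for kmer, positions in fwd.items():
        rc = reverse_complement(kmer)
        if rc not in fwd or kmer in seen_words:
            continue
        seen_words.add(kmer)
        seen_words.add(rc)
        pairs = (
            [(i, j) for a, i in enumerate(positions) for j in positions[a + 1 :]]
            if rc == kmer
            else [
                (min(i, j), max(i, j))
                for i in positions
                for j in fwd[rc]
                if i != j
            ]
        )
        for i, j in set(pairs):
            inv_seeds.append((i, L - W - j))  # transformed into rc space
    out = []
    for aln in _scan_seeds(seq, seq, direct_seeds, p, self_mode=True):
        out.append((aln, "direct"))
    for aln in _scan_seeds(seq, rcseq, inv_seeds, p):
        out.append((aln, "inverted"))
    return out


def _canonical_key(h: RepeatHit) -> tuple:
    return (
        h.copy1.start,
        h.copy1.end,
        h.copy2.start,
        h.copy2.end,
        h.orientation,
    )


def _order_copies(h: RepeatHit) -> RepeatHit:
    """Canonical ordering: copy1.start <= copy2.start.

    Swapping the copies of an inverted hit keeps copy1 on '+' by moving the
    '-' flag to the other interval; a direct hit is symmetric.
    """
    if h.copy1.start <= h.copy2.start:
        return h
    c1 = CircInterval(start=h.copy2.start, end=h.copy2.end, strand="+")
    strand2 = "-" if h.orientation == "inverted" else "+"
    c2 = CircInterval(start=h.copy1.start, end=h.copy1.end, strand=strand2)
    return replace(h, copy1=c1, copy2=c2)


def filter_and_canonicalize(
    hits: list[RepeatHit], p: AlignmentParams | None = None
) -> list[RepeatHit]:
    """Apply the E-value cutoff, drop self-identity hits, merge mirrors.

    A hit reported both as A->B and B->A counts once (canonical ordering by
    copy1.start); output is sorted by copy1.start.
    """
    p = p or AlignmentParams()
    out = {}
    for h in hits:
        if not h.cross_genome and (h.copy1.start, h.copy1.end) == (
            h.copy2.start,
            h.copy2.end,
        ):
            continue  # self-identity (incl. a region rc-matching itself)
        if h.evalue > p.e_cutoff:
            continue
        h = _order_copies(h)
        key = _canonical_key(h)
        if key not in out or h.score > out[key].score:
            out[key] = h
    return sorted(out.values(), key=lambda h: (h.copy1.start, h.copy1.end, h.copy2.start))


def _shift_interval(iv: CircInterval, shift: int, L: int) -> CircInterval:
    s = (iv.start - 1 + shift) % L + 1
    e = (iv.end - 1 + shift) % L + 1
    return CircInterval(start=s, end=e, strand=iv.strand)


def _positions_set(iv: CircInterval, L: int) -> frozenset:
    return frozenset(iv.positions(L))


def _drop_contained(hits: list[RepeatHit], L: int) -> list[RepeatHit]:
    """Remove hits whose both copies are contained in another hit's copies.

    Needed after merging the rotated search: a repeat spanning one cut is
    found truncated in that rotation and complete in the other.
    """
    if len(hits) < 2:
        return hits
    keep = [True] * len(hits)
    pos = [
        (_positions_set(h.copy1, L), _positions_set(h.copy2, L)) for h in hits
    ]
    for a in range(len(hits)):
        for b in range(len(hits)):
            if a == b or not keep[a]:
                continue
            if hits[a].orientation != hits[b].orientation:
                continue
            pa1, pa2 = pos[a]
            pb1, pb2 = pos[b]
            if pa1 < pb1 and pa2 < pb2 and hits[a].score <= hits[b].score:
                keep[a] = False
    return [h for h, k in zip(hits, keep) if k]


def find_repeats(
    g: CircularGenome, p: AlignmentParams | None = None
) -> list[RepeatHit]:
    """Full repeat search: seed, extend, E-filter, canonicalize.

    On circular genomes the search is repeated on the sequence rotated by
    L/2 so repeats spanning the origin are recovered, then deduplicated.
    """
    p = p or AlignmentParams()
    L = g.length
    hits: list[RepeatHit] = []
    rotations = [0, L // 2] if (g.circular and L >= 2 * p.word_size) else [0]
    for shift in rotations:
        seq = g.seq[shift:] + g.seq[:shift] if shift else g.seq
        for aln, orientation in _self_search(seq, p):
            h = _hit_from_raw(aln, orientation, L, L, p)
            if h.evalue > p.e_cutoff:
                continue
            if shift:
                h = replace(
                    h,
                    copy1=_shift_interval(h.copy1, shift, L),
                    copy2=_shift_interval(h.copy2, shift, L),
                )
            if (h.copy1.start, h.copy1.end) == (h.copy2.start, h.copy2.end):
                continue
            hits.append(h)
    hits = filter_and_canonicalize(hits, p)
    if len(rotations) > 1:
        hits = _drop_contained(hits, L)
    return hits
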