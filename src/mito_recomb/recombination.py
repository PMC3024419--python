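"""Recombinant genome configurations across repeats, and their evidence.

A single crossover between the two copies of a *direct* repeat resolves a
circular genome into two subgenomic circles whose sizes sum to the genome
length; each circle retains one repeat copy, now flanked by sequence that
was joined to the *other* copy in the parent molecule.  A crossover between
*inverted* repeat copies leaves one circle of unchanged size with the
intervening segment reverse-complemented.  Either way the recombinant
molecule carries two novel repeat-flank junctions that are absent from the
reference genome whenever the flanks are unique -- which is exactly what
makes junction-spanning ("chimeric") reads and junction-specific PCR
informative.

Junction labels follow the A->D (direct) and E->G (inverted) convention of
primer-survey diagrams; the reciprocal products carry the reversed labels.
Where the two copies differ (identity < 100%), each junction sequence uses
the copy physically retained at that junction; the possibility of
gene-conversion tracts in real recombinants means observed products may mix
the two variants, so the retained-copy interval is surfaced as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .circgenome import (
    CircInterval,
    CircularGenome,
    extract,
    reverse_complement,
)
from .repeat_finder import RepeatHit

__all__ = [
    "GeometryError",
    "FlankError",
    "Junction",
    "RecombinantConfig",
    "ChimeraEvidence",
    "JunctionAssay",
    "predict_products",
    "design_assay",
    "detect_chimeric_reads",
    "quantify_configurations",
    "ConfigurationRatio",
]


class GeometryError(ValueError):
    """Repeat copies overlap, wrap, or otherwise defeat the crossover model."""


class FlankError(ValueError):
    """A requested flank runs into the partner repeat copy."""


@dataclass(frozen=True)
class Junction:
    """A novel flank-repeat-flank join created by recombination.

    ``seq`` is flank1 + retained repeat copy + flank2.  The source
    intervals give the reference-genome coordinates of the three parts
    (strand '-' marks a part that appears reverse-complemented in the
    junction).
    """

    label: str
    seq: str
    flank1_source: CircInterval
    repeat_source: CircInterval
    flank2_source: CircInterval
    flank_len: int
    repeat_len: int


@dataclass
class RecombinantConfig:
    repeat: RepeatHit
    kind: str  # "two_subcircles" | "inversion"
    product_sizes: list[int]
    junctions: list[Junction]
    products: list[tuple[str, str]] = field(default_factory=list)
    primer_windows: list[CircInterval] = field(default_factory=list)


def _pos(x: int, L: int) -> int:
    """Wrap a 1-based coordinate onto the circle."""
    return (x - 1) % L + 1


def _civ(start: int, end: int, L: int, strand: str = "+") -> CircInterval:
    return CircInterval(start=_pos(start, L), end=_pos(end, L), strand=strand)


def predict_products(
    g: CircularGenome, r: RepeatHit, flank: int = 500
) -> RecombinantConfig:
    """Predict the recombinant product(s) of a crossover across ``r``.

    Direct repeat at starts s1 < s2: two circles of sizes (s2 - s1) and
    (L - (s2 - s1)).  Inverted repeat: one circle with the segment between
    the copies reverse-complemented.  Junction sequences carry ``flank`` nt
    of unique sequence on each side of the retained repeat copy.
    """
    L = g.length
    c1, c2 = r.copy1, r.copy2
    for c in (c1, c2):
        c.validate(L)
        if c.wraps:
            raise GeometryError(
                "origin-wrapping repeat copies are not supported for product "
                "prediction; rotate the genome first"
            )
    if c2.start <= c1.start:
        c1, c2 = c2, c1
    s1, e1, s2, e2 = c1.start, c1.end, c2.start, c2.end
    if s2 <= e1:
        raise GeometryError(f"repeat copies {c1} and {c2} overlap")
    if flank < 1:
        raise FlankError("flank must be >= 1")
    gap_inner = s2 - e1 - 1
    gap_outer = L - (e2 - s1 + 1)
    if flank > gap_inner or flank > gap_outer:
        raise FlankError(
            f"flank {flank} overruns the partner copy (gaps: {gap_inner} inner, "
            f"{gap_outer} outer)"
        )
    rep_len1 = e1 - s1 + 1
    rep_len2 = e2 - s2 + 1
    ex = lambda a, b, strand="+": extract(g, _civ(a, b, L, strand))
    if r.orientation == "direct":
        d = s2 - s1
        sub1 = ex(s1, s2 - 1)
        sub2 = ex(s2, s1 - 1)
        j1 = Junction(
            label="A->D",
            seq=ex(s2 - flank, s2 - 1) + ex(s1, e1) + ex(e1 + 1, e1 + flank),
            flank1_source=_civ(s2 - flank, s2 - 1, L),
            repeat_source=c1,
            flank2_source=_civ(e1 + 1, e1 + flank, L),
            flank_len=flank,
            repeat_len=rep_len1,
        )
        j2 = Junction(
            label="D->A",
            seq=ex(s1 - flank, s1 - 1) + ex(s2, e2) + ex(e2 + 1, e2 + flank),
            flank1_source=_civ(s1 - flank, s1 - 1, L),
            repeat_source=c2,
            flank2_source=_civ(e2 + 1, e2 + flank, L),
            flank_len=flank,
            repeat_len=rep_len2,
        )
        return RecombinantConfig(
            repeat=r,
            kind="two_subcircles",
            product_sizes=[d, L - d],
            junctions=[j1, j2],
            products=[("subcircle_1", sub1), ("subcircle_2", sub2)],
        )
    if r.orientation != "inverted":
        raise GeometryError(f"unknown orientation {r.orientation!r}")
    mid = g.seq[e1 : s2 - 1]
    new_seq = g.seq[:e1] + reverse_complement(mid) + g.seq[s2 - 1 :]
    gnew = CircularGenome(id=g.id + "_inv", seq=new_seq, circular=g.circular)
    exn = lambda a, b: extract(gnew, _civ(a, b, L))
    j1 = Junction(
        label="E->G",
        seq=exn(s1 - flank, e1 + flank),
        flank1_source=_civ(s1 - flank, s1 - 1, L),
        repeat_source=c1,
        flank2_source=_civ(s2 - flank, s2 - 1, L, "-"),
        flank_len=flank,
        repeat_len=rep_len1,
    )
    j2 = Junction(
        label="G->E",
        seq=exn(s2 - flank, e2 + flank),
        flank1_source=_civ(e1 + 1, e1 + flank, L, "-"),
        repeat_source=c2,
        flank2_source=_civ(e2 + 1, e2 + flank, L),
        flank_len=flank,
        repeat_len=rep_len2,
    )
    return RecombinantConfig(
        repeat=r,
        kind="inversion",
        product_sizes=[L],
        junctions=[j1, j2],
        products=[("inverted", new_seq)],
    )


# ---------------------------------------------------------------------------
# PCR assay layout


@dataclass
class JunctionAssay:
    junction_label: str
    success: bool
    reason: str = ""
    primer1_seq: str = ""
    primer2_seq: str = ""
    primer1_window: CircInterval | None = None
    primer2_window: CircInterval | None = None
    expected_product_size: int | None = None
    reference_product_sizes: list[int] = field(default_factory=list)


def _circular_occurrences(g: CircularGenome, oligo: str) -> list[tuple[int, str]]:
    """1-based start positions of ``oligo`` on either strand of the circle."""
    hay = g.seq + (g.seq[: len(oligo) - 1] if g.circular else "")
    hits = []
    for probe, strand in ((oligo, "+"), (reverse_complement(oligo), "-")):
        start = 0
        while True:
            idx = hay.find(probe, start)
            if idx < 0 or idx >= g.length:
                break
            hits.append((idx + 1, strand))
            start = idx + 1
    return hits


def _is_unique(g: CircularGenome, oligo: str) -> bool:
    return len(_circular_occurrences(g, oligo)) == 1


def _reference_products(
    g: CircularGenome, oligo1: str, oligo2: str, max_product: int
) -> list[int]:
    """Sizes of products the primer pair would give on the reference circle.

    A '+' occurrence primes rightward synthesis, a '-' occurrence leftward;
    a product needs one of each within ``max_product``.
    """
    L = g.length
    sizes = []
    occ1 = _circular_occurrences(g, oligo1)
    occ2 = _circular_occurrences(g, oligo2)
    for (a, sa), (b, sb) in [(x, y) for x in occ1 for y in occ2] + [
        (y, x) for x in occ1 for y in occ2
    ]:
        if sa == "+" and sb == "-":
            size = (b + len(oligo2) - 1 - a) % L + 1
            if size >= len(oligo1) + len(oligo2) and size <= max_product:
                sizes.append(size)
    return sorted(set(sizes))


def design_assay(
    g: CircularGenome,
    cfg: RecombinantConfig,
    primer_len: int = 20,
    max_product: int = 2000,
) -> list[JunctionAssay]:
    """Lay out a junction-specific primer pair for each recombinant junction.

    Primer windows are slid outward from the repeat boundary until their
    sequence occurs exactly once in the genome; windows that would push the
    recombinant product past ``max_product`` are a reported (non-fatal)
    design failure.  The expected recombinant product size and any product
    the pair would also give on the reference configuration are reported.
    """
    if primer_len < 15:
        raise ValueError("primer_len must be >= 15")
    assays = []
    for j in cfg.junctions:
        budget = max_product - j.repeat_len - 2 * primer_len
        if budget < 0:
            assays.append(
                JunctionAssay(
                    junction_label=j.label,
                    success=False,
                    reason="repeat too long for max_product",
                )
            )
            continue
        per_side = min(budget // 2, j.flank_len - primer_len)
        found = None
        for off1 in range(per_side + 1):
            a1 = j.flank_len - off1 - primer_len
            if a1 < 0:
                break
            p1 = j.seq[a1 : a1 + primer_len]
            if _is_unique(g, p1):
                found = (off1, p1)
                break
        if found is None:
            assays.append(
                JunctionAssay(
                    junction_label=j.label,
                    success=False,
                    reason="no unique flank within max_product upstream of the repeat",
                )
            )
            continue
        off1, p1 = found
        found2 = None
        for off2 in range(per_side + 1):
            b2 = j.flank_len + j.repeat_len + off2
            window = j.seq[b2 : b2 + primer_len]
            if len(window) < primer_len:
                break
            p2 = reverse_complement(window)
            if _is_unique(g, p2):
                found2 = (off2, p2)
                break
        if found2 is None:
            assays.append(
                JunctionAssay(
                    junction_label=j.label,
                    success=False,
                    reason="no unique flank within max_product downstream of the repeat",
                )
            )
            continue
        off2, p2 = found2
        w1 = _circular_occurrences(g, p1)[0]
        w2 = _circular_occurrences(g, p2)[0]
        win1 = _civ(w1[0], w1[0] + primer_len - 1, g.length, w1[1])
        win2 = _civ(w2[0], w2[0] + primer_len - 1, g.length, w2[1])
        assay = JunctionAssay(
            junction_label=j.label,
            success=True,
            primer1_seq=p1,
            primer2_seq=p2,
            primer1_window=win1,
            primer2_window=win2,
            expected_product_size=primer_len + off1 + j.repeat_len + off2 + primer_len,
            reference_product_sizes=_reference_products(g, p1, p2, max_product),
        )
        assays.append(assay)
        cfg.primer_windows.extend([win1, win2])
    return assays


# ---------------------------------------------------------------------------
# chimeric-read detection


@dataclass(frozen=True)
class ChimeraEvidence:
    read_id: str
    repeat_id: str
    config_label: str
    anchor1: CircInterval
    anchor2: CircInterval
    mismatches: int


def _as_pairs(reads) -> list[tuple[str, str]]:
    out = []
    for n, r in enumerate(reads):
        if hasattr(r, "seq") and hasattr(r, "id"):
            out.append((str(r.id), str(r.seq)))
        elif isinstance(r, (tuple, list)):
            out.append((str(r[0]), str(r[1])))
        else:
            out.append((f"read{n}", str(r)))
    return out


def _map_flank(iv: CircInterval, lo: int, hi: int, L: int) -> CircInterval:
    """Genome interval for junction-local offsets [lo, hi] within a flank.

    Offset 0 is the flank base adjacent to the junction start on '+'
    sources, and the flank's high-coordinate end on '-' sources (which
    appear reverse-complemented in the junction sequence).
    """
    if iv.strand == "+":
        return _civ(iv.start + lo, iv.start + hi, L)
    return _civ(iv.end - hi, iv.end - lo, L, "-")


def _junction_tables(
    g: CircularGenome, repeats: Sequence[RepeatHit], window: int
) -> list[tuple[str, Junction]]:
    tables = []
    for i, r in enumerate(repeats):
        c1, c2 = sorted([r.copy1, r.copy2], key=lambda c: c.start)
        s1, e1, s2, e2 = c1.start, c1.end, c2.start, c2.end
        gap_inner = s2 - e1 - 1
        gap_outer = g.length - (e2 - s1 + 1)
        flank = min(window, gap_inner, gap_outer)
        if flank < 1:
            continue
        cfg = predict_products(g, r, flank=flank)
        for j in cfg.junctions:
            tables.append((f"rep{i + 1}", j))
    return tables


def _reference_hit(doubled: str, L: int, read: str) -> bool:
    if len(read) > len(doubled):
        return False
    return doubled.find(read) >= 0 or doubled.find(reverse_complement(read)) >= 0


def detect_chimeric_reads(
    reads,
    g: CircularGenome,
    repeats: Sequence[RepeatHit],
    min_anchor: int = 20,
    max_mismatch: int = 0,
) -> list[ChimeraEvidence]:
    """Find reads that span a predicted recombinant junction.

    A read consistent with the reference genome (a circular substring on
    either strand, within ``max_mismatch`` edits) yields nothing.  A
    remaining read yields evidence when it matches a predicted junction
    sequence with anchors of at least ``min_anchor`` nt in the unique
    flanks on *both* sides of the repeat copy -- anchors inside the repeat
    itself cannot tell the copies apart.  One evidence record is emitted
    per read (its best junction).
    """
    pairs = _as_pairs(reads)
    if not pairs:
        return []
    L = g.length
    doubled = g.seq + (g.seq if g.circular else "")
    window = max(len(s) for _, s in pairs)
    tables = _junction_tables(g, repeats, window)
    evidence = []
    for read_id, seq in pairs:
        if max_mismatch == 0:
            if _reference_hit(doubled, L, seq):
                continue
        else:
            import edlib

            if any(
                edlib.align(s, doubled, mode="HW", k=max_mismatch)["editDistance"] >= 0
                for s in (seq, reverse_complement(seq))
            ):
                continue
        rec = None
        for rep_id, j in tables:
            for s in (seq, reverse_complement(seq)):
                loc = _match_in_junction(s, j.seq, max_mismatch)
                if loc is None:
                    continue
                start, end, dist = loc
                flen, rlen = j.flank_len, j.repeat_len
                if start <= flen - min_anchor and end >= flen + rlen + min_anchor - 1:
                    a1 = _map_flank(j.flank1_source, start, flen - 1, L)
                    a2 = _map_flank(
                        j.flank2_source, 0, end - (flen + rlen), L
                    )
                    cand = ChimeraEvidence(
                        read_id=read_id,
                        repeat_id=rep_id,
                        config_label=j.label,
                        anchor1=a1,
                        anchor2=a2,
                        mismatches=dist,
                    )
                    if rec is None or dist < rec.mismatches:
                        rec = cand
            if rec is not None and rec.mismatches == 0:
                break
        if rec is not None:
            evidence.append(rec)
    return evidence


def _match_in_junction(read: str, jseq: str, max_mismatch: int):
    """Locate ``read`` inside ``jseq``; returns (start, end, dist) or None."""
    if max_mismatch == 0:
        idx = jseq.find(read)
        if idx < 0:
            return None
        return idx, idx + len(read) - 1, 0
    import edlib

    res = edlib.align(read, jseq, mode="HW", task="locations", k=max_mismatch)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end, res["editDistance"]


# ---------------------------------------------------------------------------
# configuration stoichiometry


@dataclass(frozen=True)
class ConfigurationRatio:
    repeat_id: str
    reference_reads: int
    recombinant_reads: int
    ratio: float | None
    undefined: bool


def quantify_configurations(
    evidence: Sequence[ChimeraEvidence],
    reads,
    g: CircularGenome,
    repeats: Sequence[RepeatHit],
    min_anchor: int = 20,
) -> dict[str, ConfigurationRatio]:
    """Reference-to-recombinant read ratio for every repeat.

    Reference support counts reads that match the reference genome and span
    one of the repeat's copies with at least ``min_anchor`` nt of flank on
    both sides (the reference analogue of a junction-spanning read).  The
    ratio is reference/recombinant; it is flagged undefined when no
    recombinant reads were observed.
    """
    pairs = _as_pairs(reads)
    L = g.length
    doubled = g.seq + (g.seq if g.circular else "")
    rec_counts: dict[str, int] = {}
    for ev in evidence:
        rec_counts[ev.repeat_id] = rec_counts.get(ev.repeat_id, 0) + 1
    ref_counts = {f"rep{i + 1}": 0 for i in range(len(repeats))}
    for _, seq in pairs:
        occs = []
        for probe in (seq, reverse_complement(seq)):
            start = 0
            while True:
                idx = doubled.find(probe, start)
                if idx < 0 or idx >= L:
                    break
                occs.append(idx + 1)  # 1-based start on the circle
                start = idx + 1
        if not occs:
            continue
        n = len(seq)
        for i, r in enumerate(repeats):
            label = f"rep{i + 1}"
            spanned = False
            for c in (r.copy1, r.copy2):
                for s, e in ((c.start, c.end), (c.start + L, c.end + L)):
                    for a in occs:
                        if a <= s - min_anchor and a + n - 1 >= e + min_anchor:
                            spanned = True
            if spanned:
                ref_counts[label] += 1
    out = {}
    for i in range(len(repeats)):
        label = f"rep{i + 1}"
        rec = rec_counts.get(label, 0)
        ref = ref_counts[label]
        out[label] = ConfigurationRatio(
            repeat_id=label,
            reference_reads=ref,
            recombinant_reads=rec,
            ratio=(ref / rec) if rec > 0 else None,
            undefined=rec == 0,
        )
    return out
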