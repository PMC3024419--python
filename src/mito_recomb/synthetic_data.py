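"""Synthetic circular genomes, repeat plants, recombinant molecules, and
read pools with recorded ground truth.

Every generator is a pure function of its parameters and a seed, and emits
a truth record sufficient to recompute the expected output of every
downstream stage without re-running the generator.

Design notes
------------
* Background sequence is i.i.d. at a configurable GC content (default
  45.1%, typical of plant mitochondrial genomes).
* Planted repeat copy 2 derives from copy 1 by substitutions only -- the
  number that realises the requested percent identity, rounded to the
  nearest achievable -- placed at least 4 nt from the copy ends.  The
  three background bases flanking each side of a planted pair are forced
  to mismatch between the two copies.  Together these make the planted
  coordinates coincide with the maximal-scoring local alignment, so
  "exact boundary recovery" is well defined (real repeat boundaries are
  themselves alignment-defined).
* Reads are error-free by default (an optional uniform substitution rate
  exists for robustness tests); starts are uniform on each circular
  molecule, with molecules drawn proportionally to weight x length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .circgenome import CircInterval, CircularGenome, reverse_complement
from .recombination import predict_products
from .repeat_finder import RepeatHit

__all__ = [
    "RepeatSpec",
    "PlantedRepeat",
    "PlantedSegment",
    "SyntheticTruth",
    "Read",
    "Molecule",
    "MoleculePool",
    "PlacementError",
    "generate_genome",
    "generate_recombinant_molecules",
    "generate_reads",
    "generate_bispecies_fixture",
    "BiSpeciesTruth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Could not place all planted features without overlap."""


@dataclass(frozen=True)
class RepeatSpec:
    """A repeat pair to plant: length, identity, orientation, positions.

    ``positions`` is either None (random placement) or a pair of fixed
    1-based start coordinates for the two copies.
    """

    length: int
    identity: float = 100.0
    orientation: str = "direct"
    positions: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValueError("planted repeats must be >= 20 nt")
        if not 80.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [80, 100]")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class PlantedRepeat:
    repeat_id: str
    copy1: CircInterval
    copy2: CircInterval
    orientation: str
    identity: float  # realised identity after rounding to whole substitutions
    n_substitutions: int
    mutated_positions: tuple[int, ...]  # genome coordinates, on copy 2

    def as_hit(self, L: int) -> RepeatHit:
        """The repeat as the alignment hit a perfect search would report."""
        return RepeatHit(
            copy1=self.copy1,
            copy2=self.copy2,
            orientation=self.orientation,
            score=0.0,
            evalue=0.0,
            identity=self.identity,
            aln_length=self.copy1.length(L),
        )


@dataclass(frozen=True)
class PlantedSegment:
    label: str
    interval: CircInterval


@dataclass
class SyntheticTruth:
    genome_id: str
    seed: int
    genome_length: int
    repeats: list[PlantedRepeat] = field(default_factory=list)
    segments: list[PlantedSegment] = field(default_factory=list)
    abundance_ratio: tuple[float, float] | None = None

    def repeat(self, repeat_id: str) -> PlantedRepeat:
        for r in self.repeats:
            if r.repeat_id == repeat_id:
                return r
        raise KeyError(f"no planted repeat {repeat_id!r}")

    def to_json(self, path) -> None:
        def enc(o):
            if isinstance(o, CircInterval):
                return {"start": o.start, "end": o.end, "strand": o.strand}
            return asdict(o)

        data = {
            "genome_id": self.genome_id,
            "seed": self.seed,
            "genome_length": self.genome_length,
            "repeats": [enc(r) | {"copy1": enc(r.copy1), "copy2": enc(r.copy2)} for r in self.repeats],
            "segments": [
                {"label": s.label, "interval": enc(s.interval)} for s in self.segments
            ],
            "abundance_ratio": self.abundance_ratio,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _random_background(rng: np.random.Generator, L: int, gc: float) -> np.ndarray:
    p_gc = gc / 200.0
    p = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]  # A C G T
    return rng.choice(_BASES, size=L, p=p)


def _mutate_copy(
    rng: np.random.Generator, copy: np.ndarray, identity: float
) -> tuple[np.ndarray, list[int]]:
    """Substitute interior positions to realise the requested identity.

    Returns the mutated copy and the 0-based offsets substituted.
    Substitutions keep at least 4 intact nt from each copy end and from
    each other: under +1/-3 substitution scoring every alignment prefix
    and suffix then has positive score, so the planted span is exactly
    the maximal-scoring local alignment and boundary recovery is well
    defined.
    """
    n = len(copy)
    n_sub = int(round((100.0 - identity) / 100.0 * n))
    if n_sub == 0:
        return copy.copy(), []
    lo, hi, gap = 4, n - 5, 4
    span = hi - lo + 1 - (n_sub - 1) * gap
    if span < n_sub:
        raise ValueError(
            f"cannot place {n_sub} spaced substitutions in a {n}-nt copy"
        )
    picks = np.sort(rng.choice(span, size=n_sub, replace=False))
    offsets = [int(lo + p + i * gap) for i, p in enumerate(picks)]
    out = copy.copy()
    for off in offsets:
        choices = _BASES[_BASES != out[off]]
        out[off] = rng.choice(choices)
    return out, offsets


_COMP = dict(zip(b"ACGT", b"TGCA"))


def _revcomp_arr(a: np.ndarray) -> np.ndarray:
    out = np.array([_COMP[b] for b in a[::-1].tolist()], dtype=np.uint8)
    return out


def _place(
    rng: np.random.Generator,
    L: int,
    lengths: Sequence[int],
    occupied: list[tuple[int, int]],
    pad: int = 12,
    tries: int = 2000,
) -> list[int]:
    """Non-overlapping 0-based start offsets, kept clear of the origin."""
    starts = []
    for n in lengths:
        for _ in range(tries):
            s = int(rng.integers(pad, L - n - pad))
            if all(s + n + pad <= a or s >= b + pad for a, b in occupied):
                occupied.append((s, s + n))
                starts.append(s)
                break
        else:
            raise PlacementError(f"could not place a {n}-nt feature in {L} nt")
    return starts


def generate_genome(
    L: int,
    specs: Sequence[RepeatSpec] = (),
    segment_specs: Sequence[tuple[str, int]] = (),
    seed: int = 0,
    gc: float = 45.1,
    genome_id: str = "synthetic",
) -> tuple[CircularGenome, SyntheticTruth]:
    """A circular genome with planted repeat pairs and labelled segments.

    ``segment_specs`` is a sequence of (category label, length) pairs; the
    segments are background sequence whose coordinates are recorded in the
    truth (for partition-accounting tests).
    """
    rng = np.random.default_rng(seed)
    total = sum(s.length * 2 for s in specs) + sum(n for _, n in segment_specs)
    if total >= L:
        raise PlacementError("total planted length must be below genome length")
    arr = _random_background(rng, L, gc)
    occupied: list[tuple[int, int]] = []
    for s in specs:
        if s.positions is not None:
            for pos, n in zip(s.positions, (s.length, s.length)):
                occupied.append((pos - 1, pos - 1 + n))
    truth = SyntheticTruth(genome_id=genome_id, seed=seed, genome_length=L)
    for idx, spec in enumerate(specs):
        if spec.positions is not None:
            s1, s2 = (spec.positions[0] - 1, spec.positions[1] - 1)
        else:
            s1, s2 = sorted(_place(rng, L, [spec.length, spec.length], occupied))
        n = spec.length
        copy1 = arr[s1 : s1 + n].copy()
        mutated, offsets = _mutate_copy(rng, copy1, spec.identity)
        if spec.orientation == "inverted":
            arr[s2 : s2 + n] = _revcomp_arr(mutated)
            mut_genome = tuple(sorted(s2 + (n - 1 - off) + 1 for off in offsets))
        else:
            arr[s2 : s2 + n] = mutated
            mut_genome = tuple(sorted(s2 + off + 1 for off in offsets))
        _sharpen_boundaries(rng, arr, s1, s2, n, spec.orientation)
        c1 = CircInterval(start=s1 + 1, end=s1 + n, strand="+")
        c2 = CircInterval(
            start=s2 + 1, end=s2 + n, strand="-" if spec.orientation == "inverted" else "+"
        )
        realised = 100.0 * (n - len(offsets)) / n
        truth.repeats.append(
            PlantedRepeat(
                repeat_id=f"rep{idx + 1}",
                copy1=c1,
                copy2=c2,
                orientation=spec.orientation,
                identity=realised,
                n_substitutions=len(offsets),
                mutated_positions=mut_genome,
            )
        )
    if segment_specs:
        starts = _place(rng, L, [n for _, n in segment_specs], occupied)
        for (label, n), s in zip(segment_specs, starts):
            truth.segments.append(
                PlantedSegment(label=label, interval=CircInterval(start=s + 1, end=s + n))
            )
    g = CircularGenome(id=genome_id, seq=arr.tobytes().decode("ascii"), circular=True)
    return g, truth


def _sharpen_boundaries(
    rng: np.random.Generator,
    arr: np.ndarray,
    s1: int,
    s2: int,
    n: int,
    orientation: str,
    k: int = 3,
) -> None:
    """Force the k alignment-facing flank bases of the two copies apart.

    Without this, chance agreement of the flanking background would let a
    local alignment extend past the planted boundary.  The copy-2 side is
    edited.
    """
    L = len(arr)
    for t in range(1, k + 1):
        if orientation == "direct":
            pairs = [((s1 - t) % L, (s2 - t) % L), ((s1 + n - 1 + t) % L, (s2 + n - 1 + t) % L)]
            for p1, p2 in pairs:
                if arr[p1] == arr[p2]:
                    arr[p2] = rng.choice(_BASES[_BASES != arr[p1]])
        else:
            # copy1 left flank aligns to the complement of copy2 right flank
            pairs = [
                ((s1 - t) % L, (s2 + n - 1 + t) % L),
                ((s1 + n - 1 + t) % L, (s2 - t) % L),
            ]
            for p1, p2 in pairs:
                if arr[p2] == _COMP[arr[p1]]:
                    arr[p2] = rng.choice(_BASES[_BASES != _COMP[arr[p1]]])


# ---------------------------------------------------------------------------
# molecule pools and reads


@dataclass(frozen=True)
class Molecule:
    name: str
    seq: str
    weight: float
    circular: bool = True
    kind: str = "reference"  # "reference" | "recombinant"


@dataclass
class MoleculePool:
    molecules: list[Molecule]
    repeat_id: str | None = None
    ratio: tuple[float, float] | None = None

    @property
    def reference(self) -> Molecule:
        for m in self.molecules:
            if m.kind == "reference":
                return m
        raise ValueError("pool has no reference molecule")


def generate_recombinant_molecules(
    g: CircularGenome,
    truth: SyntheticTruth,
    repeat_id: str,
    ratio: tuple[float, float] = (100.0, 1.0),
    flank: int = 50,
) -> MoleculePool:
    """Reference plus predicted recombinant molecules at the given
    reference:recombinant weight ratio."""
    planted = truth.repeat(repeat_id)
    mols = [Molecule(name="reference", seq=g.seq, weight=ratio[0], kind="reference")]
    if ratio[1] > 0:
        cfg = predict_products(g, planted.as_hit(g.length), flank=flank)
        for name, seq in cfg.products:
            mols.append(
                Molecule(name=name, seq=seq, weight=ratio[1], kind="recombinant")
            )
    return MoleculePool(molecules=mols, repeat_id=repeat_id, ratio=ratio)


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    source: str
    start: int  # 1-based start on the source molecule ('+' orientation)
    strand: str


def generate_reads(
    pool: MoleculePool,
    depth: float,
    read_len: int,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[Read]:
    """Error-free shotgun reads from a weighted circular molecule pool.

    The expected read count is ``depth * reference_length / read_len``
    (depth is relative to the reference molecule); reads land on molecules
    proportionally to weight x length, uniformly within each circle, on a
    random strand.  Per-read source labels are recorded.
    """
    for m in pool.molecules:
        if read_len >= len(m.seq):
            raise ValueError(f"read_len {read_len} >= molecule {m.name} length")
    rng = np.random.default_rng(seed)
    ref_len = len(pool.reference.seq)
    lam = depth * ref_len / read_len
    n_reads = int(rng.poisson(lam)) if lam > 0 else 0
    if n_reads == 0:
        return []
    w = np.array([m.weight * len(m.seq) for m in pool.molecules], dtype=float)
    choices = rng.choice(len(pool.molecules), size=n_reads, p=w / w.sum())
    reads = []
    for i, mi in enumerate(choices):
        m = pool.molecules[mi]
        Lm = len(m.seq)
        start = int(rng.integers(0, Lm))
        doubled = m.seq + m.seq
        seq = doubled[start : start + read_len]
        if error_rate > 0:
            seq = _add_substitutions(rng, seq, error_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(
            Read(id=f"read{i}", seq=seq, source=m.name, start=start + 1, strand=strand)
        )
    return reads


def _add_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# bi-species fixtures


@dataclass
class BiSpeciesTruth:
    seed: int
    regions_a: list[CircInterval]
    regions_b: list[CircInterval]
    identities: list[float]
    lengths: list[int]
    # genome-B coordinates of the substitutions distinguishing each
    # region's B copy from its A copy
    mutated_positions_b: list[tuple[int, ...]] = field(default_factory=list)


def generate_bispecies_fixture(
    shared_lengths: Sequence[int],
    identities: Sequence[float],
    seed: int = 0,
    L: int = 20000,
    gc: float = 45.1,
) -> tuple[CircularGenome, CircularGenome, BiSpeciesTruth]:
    """Two unrelated genomes sharing only the specified planted regions.

    Region copies in genome B derive from those in genome A by interior
    substitutions realising the requested identities; flanks are random
    background and therefore unique within and between genomes (with
    overwhelming probability at these lengths).
    """
    if len(shared_lengths) != len(identities):
        raise ValueError("shared_lengths and identities must have equal length")
    rng = np.random.default_rng(seed)
    arr_a = _random_background(rng, L, gc)
    arr_b = _random_background(rng, L, gc)
    occ_a: list[tuple[int, int]] = []
    occ_b: list[tuple[int, int]] = []
    starts_a = _place(rng, L, shared_lengths, occ_a, pad=200)
    starts_b = _place(rng, L, shared_lengths, occ_b, pad=200)
    truth = BiSpeciesTruth(
        seed=seed, regions_a=[], regions_b=[], identities=[], lengths=list(shared_lengths)
    )
    for n, ident, sa, sb in zip(shared_lengths, identities, starts_a, starts_b):
        region = rng.choice(_BASES, size=n)
        arr_a[sa : sa + n] = region
        mutated, offsets = _mutate_copy(rng, region, ident)
        arr_b[sb : sb + n] = mutated
        # sharpen pair boundaries across genomes (direct orientation)
        for t in range(1, 4):
            for p1, p2 in (
                ((sa - t) % L, (sb - t) % L),
                ((sa + n - 1 + t) % L, (sb + n - 1 + t) % L),
            ):
                if arr_a[p1] == arr_b[p2]:
                    arr_b[p2] = rng.choice(_BASES[_BASES != arr_a[p1]])
        truth.regions_a.append(CircInterval(start=sa + 1, end=sa + n))
        truth.regions_b.append(CircInterval(start=sb + 1, end=sb + n))
        truth.identities.append(100.0 * (n - len(offsets)) / n)
        truth.mutated_positions_b.append(tuple(sb + off + 1 for off in offsets))
    gA = CircularGenome(id="speciesA", seq=arr_a.tobytes().decode(), circular=True)
    gB = CircularGenome(id="speciesB", seq=arr_b.tobytes().decode(), circular=True)
    return gA, gB, truth
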