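"""Shared fixtures: published repeat coordinates and small synthetic pools."""

from __future__ import annotations

import pytest

from mito_recomb.circgenome import CircInterval
from mito_recomb.repeat_finder import RepeatHit
from mito_recomb.synthetic_data import (
    RepeatSpec,
    generate_genome,
    generate_reads,
    generate_recombinant_molecules,
)

GENOME_LENGTH = 401_262

# The six representative repeats of the Vigna radiata mitochondrial genome:
# (name, length, orientation, percent identity, copy1 start/end, copy2 start/end)
SIX_REPEATS = [
    ("A", 175, "direct", 100, 120320, 120494, 331059, 331233),
    ("B", 104, "inverted", 98, 232468, 232571, 342673, 342776),
    ("C", 84, "direct", 100, 94981, 95064, 345737, 345820),
    ("D", 80, "inverted", 93, 148952, 149031, 161696, 161775),
    ("E", 53, "direct", 100, 335325, 335377, 392959, 393011),
    ("F", 38, "inverted", 100, 60480, 60517, 169122, 169159),
]


def six_repeat_hits() -> list[RepeatHit]:
    hits = []
    for name, length, orient, ident, s1, e1, s2, e2 in SIX_REPEATS:
        hits.append(
            RepeatHit(
                copy1=CircInterval(start=s1, end=e1),
                copy2=CircInterval(
                    start=s2, end=e2, strand="-" if orient == "inverted" else "+"
                ),
                orientation=orient,
                score=float(length),
                evalue=0.0,
                identity=float(ident),
                aln_length=length,
            )
        )
    return hits


@pytest.fixture(scope="session")
def direct_repeat_pool():
    """6-kb genome with one 175-nt direct repeat, 50:1 reference:recombinant
    molecule pool, and an error-free read pool."""
    g, truth = generate_genome(
        6000,
        [RepeatSpec(175, 100.0, "direct", positions=(1500, 4500))],
        seed=11,
    )
    hit = truth.repeats[0].as_hit(g.length)
    pool = generate_recombinant_molecules(g, truth, "rep1", ratio=(50, 1))
    reads = generate_reads(pool, depth=600, read_len=350, seed=7)
    return g, truth, hit, pool, reads
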