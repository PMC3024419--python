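"""Non-redundant repeat coverage, repeat counting, and length histograms.

Coverage is a per-position measure: a genomic site covered by two or more
overlapping repeat copies is counted once.  Sites are classified by the
size class of the repeats covering them (short < threshold, large >=
threshold, or both: "short within large"), and the four classes partition
the genome exactly.

Repeat *number* follows the unique begin-end coordinate convention: the
count of distinct (start, end) pairs over all hit copies.  For a k-copy
repeat family this count ranges from k (perfect family: every pairwise hit
reports the same coordinates on a given copy) to k*(k-1) (imperfect,
variably sized copies: every pairwise hit reports distinct coordinates on
each of its two copies); :func:`family_coordinate_bounds` derives both
bounds by explicit enumeration over copy pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circgenome import CircInterval
from .repeat_finder import RepeatHit

__all__ = [
    "RepeatCoverageProfile",
    "coverage_profile",
    "count_unique_coordinates",
    "family_coordinate_bounds",
    "length_histogram",
    "plot_coverage",
]


@dataclass(frozen=True)
class RepeatCoverageProfile:
    genome_length: int
    covered_short_only: int
    covered_large_only: int
    covered_short_within_large: int
    non_repetitive: int
    n_hits_short: int
    n_hits_large: int
    percent_covered: float

    def __post_init__(self) -> None:
        total = (
            self.covered_short_only
            + self.covered_large_only
            + self.covered_short_within_large
            + self.non_repetitive
        )
        if total != self.genome_length:
            raise ValueError(
                f"coverage classes sum to {total}, not genome length {self.genome_length}"
            )

    def as_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "covered_short_only": self.covered_short_only,
            "covered_large_only": self.covered_large_only,
            "covered_short_within_large": self.covered_short_within_large,
            "non_repetitive": self.non_repetitive,
            "n_hits_short": self.n_hits_short,
            "n_hits_large": self.n_hits_large,
            "percent_covered": self.percent_covered,
        }

    def to_tsv(self, path) -> None:
        pd.Series(self.as_dict()).to_csv(path, sep="\t", header=False)


def _mark(mask: np.ndarray, iv: CircInterval, L: int) -> None:
    iv.validate(L)
    if iv.wraps:
        mask[iv.start - 1 :] = True
        mask[: iv.end] = True
    else:
        mask[iv.start - 1 : iv.end] = True


def _hit_length(h: RepeatHit, L: int) -> int:
    # alignment length when recorded, else the copy-1 span
    return h.aln_length if h.aln_length is not None else h.copy1.length(L)


def coverage_profile(
    repeats: Iterable[RepeatHit], L: int, size_threshold: int = 1000
) -> RepeatCoverageProfile:
    """Classify every genomic position by the size class of covering repeats.

    A hit contributes both of its copies; a hit belongs to the short or
    large class by its own alignment length (a position decides the
    short-within-large class by being covered by one hit of each class).
    Duplicate hits in the input change nothing.
    """
    if size_threshold <= 0:
        raise ValueError("size_threshold must be positive")
    repeats = list(repeats)
    short = np.zeros(L, dtype=bool)
    large = np.zeros(L, dtype=bool)
    n_short = n_large = 0
    seen = set()
    for h in repeats:
        key = (
            h.copy1.start, h.copy1.end, h.copy2.start, h.copy2.end, h.orientation,
        )
        dup = key in seen
        seen.add(key)
        mask = short if _hit_length(h, L) < size_threshold else large
        for iv in (h.copy1, h.copy2):
            _mark(mask, iv, L)
        if not dup:
            if _hit_length(h, L) < size_threshold:
                n_short += 1
            else:
                n_large += 1
    both = short & large
    short_only = int((short & ~large).sum())
    large_only = int((large & ~short).sum())
    within = int(both.sum())
    non_rep = int(L - short_only - large_only - within)
    return RepeatCoverageProfile(
        genome_length=L,
        covered_short_only=short_only,
        covered_large_only=large_only,
        covered_short_within_large=within,
        non_repetitive=non_rep,
        n_hits_short=n_short,
        n_hits_large=n_large,
        percent_covered=100.0 * (L - non_rep) / L,
    )


def count_unique_coordinates(hits: Iterable[RepeatHit]) -> int:
    """Number of distinct (start, end) pairs over all hit copies."""
    coords = set()
    for h in hits:
        coords.add((h.copy1.start, h.copy1.end))
        coords.add((h.copy2.start, h.copy2.end))
    return len(coords)


def family_coordinate_bounds(k: int) -> tuple[int, int]:
    """Bounds on unique begin-end coordinates for a k-copy repeat family.

    Derived by enumerating all unordered copy pairs.  Minimum: a perfect
    family, where every hit involving copy c reports the same coordinates
    on c, so distinct coordinates = the copies themselves.  Maximum: an
    imperfect, variably sized family, where each pairwise hit reports its
    own coordinates on each of its two copies.
    """
    if k < 2:
        raise ValueError("a repeat family needs at least 2 copies")
    pairs = list(combinations(range(k), 2))
    perfect = set()
    variable = set()
    for pair in pairs:
        for copy in pair:
            perfect.add(copy)  # same coords for this copy in every hit
            variable.add((pair, copy))  # hit-specific coords on this copy
    return len(perfect), len(variable)


def length_histogram(
    repeats: Iterable[RepeatHit], bin_width: int, L: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of repeat alignment lengths.

    Returns ``(counts, bin_edges)`` with bins ``[i*bin_width,
    (i+1)*bin_width)``; the total count equals the number of input hits.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = [
        _hit_length(h, L if L is not None else max(h.copy1.end, h.copy2.end))
        for h in repeats
    ]
    if not lengths:
        return np.array([], dtype=int), np.array([0])
    n_bins = max(lengths) // bin_width + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return counts, edges


def plot_coverage(profile: RepeatCoverageProfile, path) -> None:
    """Stacked bar of the coverage classes (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = [
        ("short only", profile.covered_short_only, "tab:blue"),
        ("short within large", profile.covered_short_within_large, "tab:green"),
        ("large only", profile.covered_large_only, "tab:red"),
        ("non-repetitive", profile.non_repetitive, "white"),
    ]
    fig, ax = plt.subplots(figsize=(2.5, 5))
    bottom = 0
    for label, n, color in classes:
        ax.bar([0], [n], bottom=bottom, color=color, edgecolor="black", label=label)
        bottom += n
    ax.set_ylabel("nucleotides")
    ax.set_xticks([])
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
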