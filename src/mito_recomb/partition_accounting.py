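"""Mutually exclusive genome-content partition accounting.

Every position of the genome is assigned to exactly one top-level category
-- conserved syntenic, chloroplast-like, nuclear-like, mitochondrial-like,
or uncharacterized -- by a configurable precedence order, so the category
counts always sum exactly to the genome length.  Sub-features (protein
exons, cis-spliced introns, rRNA, tRNA) are reported informationally; they
live inside the conserved syntenic class and take no part in the exactness
invariant.

Percentages are printed to one decimal.  Round-half-up matches the usual
publication style; banker's rounding is available as an alternative mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circgenome import CircInterval

__all__ = [
    "TOP_LEVEL",
    "SUB_FEATURES",
    "DEFAULT_PRECEDENCE",
    "PartitionReport",
    "percent",
    "partition_genome",
    "report_from_totals",
]

TOP_LEVEL = (
    "conserved_syntenic",
    "mitochondrial_like",
    "chloroplast_like",
    "nuclear_like",
    "uncharacterized",
)
SUB_FEATURES = ("protein_exons", "cis_spliced_introns", "rRNA", "tRNA")

# highest first; mitochondrial-like is the residual similarity class
DEFAULT_PRECEDENCE = (
    "conserved_syntenic",
    "chloroplast_like",
    "nuclear_like",
    "mitochondrial_like",
)


def percent(count: int, L: int, mode: str = "half_up") -> float:
    """100*count/L rounded to one decimal (half-up by default)."""
    if L <= 0:
        raise ValueError("genome length must be positive")
    if not 0 <= count <= L:
        raise ValueError(f"count {count} outside [0, {L}]")
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_HALF_EVEN
    q = (Decimal(100) * Decimal(count) / Decimal(L)).quantize(
        Decimal("0.1"), rounding=rounding
    )
    return float(q)


@dataclass
class PartitionReport:
    genome_length: int
    counts: dict[str, int]
    sub_counts: dict[str, int] = field(default_factory=dict)
    rounding: str = "half_up"

    def __post_init__(self) -> None:
        total = sum(self.counts.get(c, 0) for c in TOP_LEVEL)
        if total != self.genome_length:
            raise ValueError(
                f"top-level categories sum to {total}, not genome length "
                f"{self.genome_length}"
            )

    @property
    def percents(self) -> dict[str, float]:
        return {
            c: percent(self.counts.get(c, 0), self.genome_length, self.rounding)
            for c in TOP_LEVEL
        }

    @property
    def sub_percents(self) -> dict[str, float]:
        return {
            c: percent(n, self.genome_length, self.rounding)
            for c, n in self.sub_counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": c, "nucleotides": n, "percent_genome": p}
            for (c, n, p) in (
                (c, self.sub_counts[c], self.sub_percents[c])
                for c in SUB_FEATURES
                if c in self.sub_counts
            )
        ]
        rows += [
            {
                "feature": c,
                "nucleotides": self.counts.get(c, 0),
                "percent_genome": self.percents[c],
            }
            for c in TOP_LEVEL
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _mark(mask: np.ndarray, ivs: Iterable[CircInterval], L: int) -> None:
    for iv in ivs:
        iv.validate(L)
        if iv.wraps:
            mask[iv.start - 1 :] = True
            mask[: iv.end] = True
        else:
            mask[iv.start - 1 : iv.end] = True


def partition_genome(
    L: int,
    feature_sets: Mapping[str, Sequence[CircInterval]],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    rounding: str = "half_up",
) -> PartitionReport:
    """Assign every position to one top-level category by precedence.

    ``feature_sets`` maps category labels to interval lists.  Labels in
    ``SUB_FEATURES`` are tallied informationally.  Positions covered by no
    category are uncharacterized.  Unknown labels raise ``ValueError``.
    """
    known = set(TOP_LEVEL) | set(SUB_FEATURES)
    for label in feature_sets:
        if label not in known:
            raise ValueError(f"unknown feature label {label!r}")
    top_labels = [l for l in feature_sets if l in TOP_LEVEL]
    for label in top_labels:
        if label != "uncharacterized" and label not in precedence:
            raise ValueError(f"precedence does not cover supplied label {label!r}")
    codes = np.zeros(L, dtype=np.int8)  # 0 = uncharacterized
    order = {label: i + 1 for i, label in enumerate(precedence)}
    # paint lowest precedence first so higher precedence overwrites
    for label in sorted(top_labels, key=lambda l: order.get(l, 0), reverse=True):
        if label == "uncharacterized":
            continue
        mask = np.zeros(L, dtype=bool)
        _mark(mask, feature_sets[label], L)
        codes[mask] = order[label]
    counts = {c: 0 for c in TOP_LEVEL}
    counts["uncharacterized"] = int((codes == 0).sum())
    for label, code in order.items():
        counts[label] = int((codes == code).sum())
    sub_counts = {}
    for label in feature_sets:
        if label in SUB_FEATURES:
            mask = np.zeros(L, dtype=bool)
            _mark(mask, feature_sets[label], L)
            sub_counts[label] = int(mask.sum())
    return PartitionReport(
        genome_length=L, counts=counts, sub_counts=sub_counts, rounding=rounding
    )


def report_from_totals(
    totals: Mapping[str, int],
    L: int | None = None,
    sub_totals: Mapping[str, int] | None = None,
    rounding: str = "half_up",
) -> PartitionReport:
    """Build a report from pre-classified per-category nucleotide totals.

    When ``L`` is omitted it is the sum of the supplied top-level totals;
    when given, any shortfall is assigned to ``uncharacterized`` if that
    category was not supplied.
    """
    counts = {c: int(totals.get(c, 0)) for c in TOP_LEVEL}
    supplied = sum(counts.values())
    if L is None:
        L = supplied
    elif "uncharacterized" not in totals:
        counts["uncharacterized"] = L - supplied
    return PartitionReport(
        genome_length=L,
        counts=counts,
        sub_counts=dict(sub_totals or {}),
        rounding=rounding,
    )
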