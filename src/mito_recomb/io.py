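"""Readers and writers for the standard interchange formats.

FASTA goes through Biopython.  Repeat lists travel as a small GFF3 dialect
(one feature per repeat copy, paired through a shared ``Parent`` attribute,
with orientation and percent-identity attributes) or as a TSV with one row
per repeat pair.  Feature-category intervals for partition accounting are
read from GFF3 (``category`` attribute or the feature type column) or BED.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circgenome import CircInterval, CircularGenome
from .repeat_finder import RepeatHit

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_repeats_gff",
    "read_repeats_gff",
    "write_repeats_tsv",
    "write_bed",
    "read_feature_intervals",
]


def read_fasta(path, circular: bool | Mapping[str, bool] = True) -> list[CircularGenome]:
    """Read one or more FASTA records as :class:`CircularGenome` objects.

    FASTA has no notion of topology, so circularity is declared out of band:
    either one flag for every record or a mapping from record id to flag.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circ = circular if isinstance(circular, bool) else bool(circular.get(rec.id, True))
        genomes.append(CircularGenome(id=rec.id, seq=str(rec.seq), circular=circ))
    return genomes


def write_fasta(genomes: Iterable[CircularGenome], path) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.id, description="circular" if g.circular else "linear")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def _gff_escape(v) -> str:
    return str(v).replace(";", "%3B").replace("=", "%3D")


def write_repeats_gff(hits: Iterable[RepeatHit], genome_id: str, path) -> None:
    """Write repeat pairs as GFF3: one ``dispersed_repeat`` feature per copy."""
    lines = ["##gff-version 3"]
    for n, h in enumerate(hits, start=1):
        parent = f"rep{n:04d}"
        for k, iv in ((1, h.copy1), (2, h.copy2)):
            attrs = (
                f"ID={parent}_c{k};Parent={parent};copy={k};"
                f"orientation={h.orientation};identity={h.identity:.1f};"
                f"aln_length={h.aln_length};score={h.score};evalue={h.evalue:.3g}"
            )
            lines.append(
                "\t".join(
                    [
                        _gff_escape(genome_id),
                        "mito-recomb",
                        "dispersed_repeat",
                        str(iv.start),
                        str(iv.end),
                        f"{h.score}",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> dict:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_repeats_gff(path) -> list[RepeatHit]:
    """Reconstruct repeat pairs from the GFF3 dialect written by this package."""
    copies: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9 or cols[2] != "dispersed_repeat":
            continue
        attrs = _parse_attrs(cols[8])
        parent = attrs.get("Parent", attrs.get("ID", ""))
        entry = copies.setdefault(parent, {"attrs": attrs})
        entry[int(attrs.get("copy", len(entry)))] = CircInterval(
            start=int(cols[3]), end=int(cols[4]), strand=cols[6]
        )
        entry["attrs"] = attrs
    hits = []
    for parent in sorted(copies):
        entry = copies[parent]
        if 1 not in entry or 2 not in entry:
            raise ValueError(f"repeat {parent!r} lacks one of its two copies")
        a = entry["attrs"]
        hits.append(
            RepeatHit(
                copy1=entry[1],
                copy2=entry[2],
                orientation=a.get("orientation", "direct"),
                score=float(a.get("score", 0)),
                evalue=float(a.get("evalue", 0)),
                identity=float(a.get("identity", 100.0)),
                aln_length=int(a.get("aln_length", 0)) or None,
            )
        )
    return hits


def write_repeats_tsv(hits: Iterable[RepeatHit], path) -> None:
    """One row per repeat pair, mirroring the published table layout."""
    rows = []
    for n, h in enumerate(hits, start=1):
        rows.append(
            {
                "repeat": f"rep{n:04d}",
                "length": h.aln_length,
                "orientation": h.orientation,
                "percent_identity": round(h.identity, 1),
                "copy1_start": h.copy1.start,
                "copy1_end": h.copy1.end,
                "copy2_start": h.copy2.start,
                "copy2_end": h.copy2.end,
                "score": h.score,
                "evalue": h.evalue,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(intervals: Iterable[tuple[str, CircInterval]], L: int, path) -> None:
    """BED6 (0-based half-open).  Wrapping intervals split into two lines."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for name_iv in intervals:
            name, iv = name_iv
            if iv.wraps:
                pieces = [(iv.start - 1, L), (0, iv.end)]
            else:
                pieces = [(iv.start - 1, iv.end)]
            for lo, hi in pieces:
                w.writerow(["genome", lo, hi, name, 0, iv.strand])


def read_feature_intervals(path) -> dict[str, list[CircInterval]]:
    """Read labelled intervals for partition accounting.

    GFF3: label is the ``category`` attribute when present, else column 3.
    BED (4+ columns, detected by extension): label is the name column.
    """
    path = Path(path)
    out: dict[str, list[CircInterval]] = {}
    if path.suffix.lower() == ".bed":
        for line in path.read_text().splitlines():
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            label = cols[3] if len(cols) > 3 else "feature"
            strand = cols[5] if len(cols) > 5 else "+"
            out.setdefault(label, []).append(
                CircInterval(start=int(cols[1]) + 1, end=int(cols[2]), strand=strand)
            )
        return out
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            continue
        attrs = _parse_attrs(cols[8]) if len(cols) > 8 else {}
        label = attrs.get("category", cols[2])
        strand = cols[6] if len(cols) > 6 and cols[6] in "+-" else "+"
        out.setdefault(label, []).append(
            CircInterval(start=int(cols[3]), end=int(cols[4]), strand=strand)
        )
    return out
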