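"""Germline gene sets: loading, validation, locus ordering, coordinate arithmetic.

A :class:`GermlineSegment` is a named germline gene or allele.  Segments may
carry a nucleotide sequence, locus coordinates (position in bp and length in
nt), or both.  Coordinate-only records are used for the packaged IGHD locus
table, where ``position`` is the gene's higher-coordinate endpoint and the
gene body extends toward decreasing coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GermlineSegment",
    "GermlineSet",
    "load_germline_fasta",
    "load_locus_table",
    "packaged_locus_table",
    "rank_by_locus",
    "inter_gene_gap",
]

_VALID_BASES = frozenset("ACGT")
_ALLELE_SUFFIX = re.compile(r"[*+].*$")


def default_allele_group(name: str) -> str:
    """Gene-level group of an allele name: everything before the first ``*``/``+``."""
    return _ALLELE_SUFFIX.sub("", name)


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene or allele.

    Parameters
    ----------
    name:
        Unique identifier within a set (e.g. ``D10*2``).
    sequence:
        Nucleotide string over ``{A, C, G, T}``; optional for coordinate-only
        records.
    position:
        Locus coordinate in bp of the gene's higher-coordinate endpoint.
    length:
        Gene length in nt.  Derived from ``sequence`` when present.
    imgt_name:
        Optional canonical database name.
    allele_group:
        Identifier grouping alleles of one gene.  Defaults to ``name``
        stripped of its allele suffix.
    """

    name: str
    sequence: Optional[str] = None
    position: Optional[int] = None
    length: Optional[int] = None
    imgt_name: Optional[str] = None
    allele_group: str = field(default="")

    def __post_init__(self) -> None:
        if self.sequence is not None:
            seq = self.sequence.upper()
            object.__setattr__(self, "sequence", seq)
            if not seq:
                raise ValueError(f"segment {self.name!r}: empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"segment {self.name!r}: non-ACGT characters {sorted(bad)!r}"
                )
            if self.length is None:
                object.__setattr__(self, "length", len(seq))
            elif self.length != len(seq):
                raise ValueError(
                    f"segment {self.name!r}: length {self.length} != |sequence| {len(seq)}"
                )
        elif self.length is None:
            raise ValueError(f"segment {self.name!r}: needs a sequence or a length")
        if not self.allele_group:
            object.__setattr__(self, "allele_group", default_allele_group(self.name))


class GermlineSet:
    """Ordered collection of :class:`GermlineSegment` of one kind (V, D or J)."""

    def __init__(self, segments: Iterable[GermlineSegment], kind: str = "D"):
        if kind not in {"V", "D", "J"}:
            raise ValueError(f"kind must be V, D or J, got {kind!r}")
        self.segments = list(segments)
        self.kind = kind
        names = [s.name for s in self.segments]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate segment names: {sorted(dupes)!r}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[GermlineSegment]:
        return iter(self.segments)

    def __getitem__(self, name: str) -> GermlineSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def sequences(self) -> dict[str, str]:
        """name -> sequence for all segments that carry a sequence."""
        return {s.name: s.sequence for s in self.segments if s.sequence is not None}

    def distinct_sequences(self) -> "GermlineSet":
        """Collapse segments with identical sequences to the first representative."""
        seen: dict[str, GermlineSegment] = {}
        for seg in self.segments:
            if seg.sequence is None:
                continue
            seen.setdefault(seg.sequence, seg)
        return GermlineSet(seen.values(), kind=self.kind)


def load_germline_fasta(path: str | Path, kind: str) -> GermlineSet:
    """Load a germline gene set from FASTA.

    Headers are parsed as ``name`` or ``name|allele_group``; sequences are
    uppercased and validated to be over ``{A, C, G, T}``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    segments = []
    for rec in records:
        fields = rec.description.split("|")
        name = fields[0].strip() or rec.id
        group = fields[1].strip() if len(fields) > 1 and fields[1].strip() else ""
        segments.append(
            GermlineSegment(name=name, sequence=str(rec.seq), allele_group=group)
        )
    return GermlineSet(segments, kind=kind)


def load_locus_table(path: str | Path, kind: str = "D") -> GermlineSet:
    """Load a locus coordinate table (TSV: name, imgt_name, position, length).

    Short display names may repeat (duplicated genes share a label); segments
    are keyed by their unique ``imgt_name`` and keep the short label as their
    ``allele_group``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "imgt_name": str})
    required = {"name", "imgt_name", "position", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus table {path} lacks columns {sorted(missing)!r}")
    segments = [
        GermlineSegment(
            name=row.imgt_name,
            imgt_name=row.imgt_name,
            position=int(row.position),
            length=int(row.length),
            allele_group=row.name,
        )
        for row in df.itertuples()
    ]
    return GermlineSet(segments, kind=kind)


def packaged_locus_table() -> GermlineSet:
    """The bundled human IGHD locus coordinate table (27 entries)."""
    with resources.as_file(
        resources.files("dscout").joinpath("data/ighd_locus.tsv")
    ) as p:
        return load_locus_table(p)


def rank_by_locus(gset: GermlineSet) -> list[str]:
    """Order segment names by strictly decreasing locus position.

    This is the canonical locus order used to index the tandem matrix:
    the first gene has the largest position.
    """
    missing = [s.name for s in gset if s.position is None]
    if missing:
        raise ValueError(f"segments without position: {missing!r}")
    positions = [s.position for s in gset]
    if len(set(positions)) != len(positions):
        raise ValueError("tied locus positions")
    return [s.name for s in sorted(gset, key=lambda s: -s.position)]


def inter_gene_gap(a: GermlineSegment, b: GermlineSegment) -> int:
    """Length of the genomic segment separating gene ``a`` from the downstream gene ``b``.

    Positions mark each gene's higher-coordinate endpoint and genes extend
    toward decreasing coordinates, so the gap is
    ``position(a) - length(a) - position(b)``.
    """
    for seg in (a, b):
        if seg.position is None or seg.length is None:
            raise ValueError(f"segment {seg.name!r} lacks position or length")
    if a.position <= b.position:
        raise ValueError(f"{a.name!r} does not precede {b.name!r} in locus order")
    gap = a.position - a.length - b.position
    if gap < 0:
        raise ValueError(f"overlapping or ill-ordered genes {a.name!r}, {b.name!r}")
    return gap
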