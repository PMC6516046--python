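"""CDR3 preprocessing: cluster similar CDR3s, build consensus, trim V/J remnants.

The product is the trimmed consensus set (``ConsensusCDR3Set``): raw CDR3s are
clustered at a small Hamming radius to absorb amplification/sequencing errors,
each cluster is collapsed to a count-weighted consensus, and germline V-gene
suffixes / J-gene prefixes are stripped from the consensus ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .germline import GermlineSet

__all__ = [
    "CDR3Record",
    "ConsensusCDR3Set",
    "PreprocessParams",
    "cluster_cdr3s",
    "cluster_consensus",
    "trim_vj",
    "build_cdr3_star",
    "read_cdr3_fasta",
    "write_cdr3_star_fasta",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CDR3Record:
    """One distinct CDR3 nucleotide sequence with its multiplicity."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"record {self.id!r}: non-ACGT characters {sorted(bad)!r}")
        if self.count < 1:
            raise ValueError(f"record {self.id!r}: count must be >= 1")


@dataclass
class ConsensusCDR3Set:
    """The trimmed consensus strings with per-string provenance.

    ``strings`` may contain repeats; ``size`` is the number of strings and is
    the normalizer for the common-k-mer rule downstream.
    """

    strings: list[str]
    provenance: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [[] for _ in self.strings]
        if len(self.provenance) != len(self.strings):
            raise ValueError("provenance length must match strings length")

    @property
    def size(self) -> int:
        return len(self.strings)

    def __len__(self) -> int:
        return len(self.strings)

    def __iter__(self):
        return iter(self.strings)

    def subset(self, indices: Sequence[int]) -> "ConsensusCDR3Set":
        return ConsensusCDR3Set(
            [self.strings[i] for i in indices],
            [self.provenance[i] for i in indices],
        )


@dataclass(frozen=True)
class PreprocessParams:
    max_mismatch: int = 3
    min_anchor: int = 5
    max_mismatch_rate: float = 0.1


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_cdr3s(
    records: Sequence[CDR3Record], max_mismatch: int = 3
) -> list[list[CDR3Record]]:
    """Partition records into connected components of the Hamming graph.

    Edges join equal-length sequences at Hamming distance <= ``max_mismatch``;
    sequences of unequal length never share an edge.  Candidate pairs are
    found by the pigeonhole banding trick: split each sequence into
    ``max_mismatch + 1`` bands — two sequences within the radius agree on at
    least one band.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    records = list(records)
    uf = _UnionFind(len(records))
    by_length: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        by_length.setdefault(len(rec.sequence), []).append(i)

    n_bands = max_mismatch + 1
    for length, idxs in by_length.items():
        bounds = np.linspace(0, length, n_bands + 1, dtype=int)
        for b in range(n_bands):
            lo, hi = bounds[b], bounds[b + 1]
            if lo == hi:
                continue
            buckets: dict[str, list[int]] = {}
            for i in idxs:
                buckets.setdefault(records[i].sequence[lo:hi], []).append(i)
            for members in buckets.values():
                if len(members) < 2:
                    continue
                anchorable = members
                for x in range(len(anchorable)):
                    i = anchorable[x]
                    for y in range(x + 1, len(anchorable)):
                        j = anchorable[y]
                        if uf.find(i) == uf.find(j):
                            continue
                        if (
                            hamming(records[i].sequence, records[j].sequence)
                            <= max_mismatch
                        ):
                            uf.union(i, j)

    clusters: dict[int, list[CDR3Record]] = {}
    for i, rec in enumerate(records):
        clusters.setdefault(uf.find(i), []).append(rec)
    return list(clusters.values())


def cluster_consensus(cluster: Sequence[CDR3Record]) -> str:
    """Count-weighted per-position plurality consensus of an equal-length cluster.

    Ties are broken by the base of the highest-count member, then
    alphabetically, so the consensus is deterministic.
    """
    if not cluster:
        raise ValueError("empty cluster")
    length = len(cluster[0].sequence)
    if any(len(r.sequence) != length for r in cluster):
        raise ValueError("cluster members must have equal length")
    if len(cluster) == 1:
        return cluster[0].sequence
    top = max(cluster, key=lambda r: r.count)
    bases = "ACGT"
    out = []
    for pos in range(length):
        weights = dict.fromkeys(bases, 0)
        for rec in cluster:
            weights[rec.sequence[pos]] += rec.count
        best = max(weights.values())
        tied = sorted(b for b, w in weights.items() if w == best)
        if len(tied) == 1:
            out.append(tied[0])
        elif top.sequence[pos] in tied:
            out.append(top.sequence[pos])
        else:
            out.append(tied[0])
    return "".join(out)


def _encode(strings: Sequence[str], width: int, align_right: bool = False) -> np.ndarray:
    """Byte matrix of ``strings`` padded with 0 to ``width`` columns."""
    arr = np.zeros((len(strings), width), dtype=np.uint8)
    for i, s in enumerate(strings):
        row = np.frombuffer(s.encode(), dtype=np.uint8)
        if align_right:
            arr[i, width - len(row):] = row
        else:
            arr[i, : len(row)] = row
    return arr


def _batch_longest_flank(
    strings: Sequence[str],
    flanks: Sequence[str],
    from_start: bool,
    min_anchor: int,
    max_mismatch_rate: float,
) -> np.ndarray:
    """Per string, the longest prefix (or suffix) matching a flank within the
    mismatch-rate budget.

    ``from_start=True`` matches string prefixes against flank suffixes (V-gene
    trimming); ``from_start=False`` matches string suffixes against flank
    prefixes (J-gene trimming).  Returns the matched length per string (0 when
    none).
    """
    if not strings or not flanks:
        return np.zeros(len(strings), dtype=int)
    lens = np.array([len(s) for s in strings])
    width = int(lens.max())
    if width == 0:
        return np.zeros(len(strings), dtype=int)
    arr = _encode(strings, width, align_right=not from_start)
    best = np.zeros(len(strings), dtype=int)
    max_flank = max(len(f) for f in flanks)
    for a in range(min_anchor, min(width, max_flank) + 1):
        allowed = int(max_mismatch_rate * a)
        ok_len = lens >= a
        for f in flanks:
            if len(f) < a:
                continue
            if from_start:
                probe = np.frombuffer(f[-a:].encode(), dtype=np.uint8)
                mism = (arr[:, :a] != probe).sum(axis=1)
            else:
                probe = np.frombuffer(f[:a].encode(), dtype=np.uint8)
                mism = (arr[:, width - a:] != probe).sum(axis=1)
            hit = ok_len & (mism <= allowed)
            best[hit & (best < a)] = a
    return best


def trim_vj(
    consensus: str,
    v_set: Optional[GermlineSet],
    j_set: Optional[GermlineSet],
    min_anchor: int = 5,
    max_mismatch_rate: float = 0.1,
) -> str:
    """Strip the V-gene suffix and J-gene prefix from a consensus CDR3.

    Removes the longest consensus prefix matching a suffix of some V gene
    (Hamming mismatch rate <= ``max_mismatch_rate``, length >= ``min_anchor``),
    then the longest remaining suffix matching a prefix of some J gene.
    Returns the remainder; an empty result means the string was entirely
    germline-encoded.
    """
    return _batch_trim_vj([consensus], v_set, j_set, min_anchor, max_mismatch_rate)[0]


def _batch_trim_vj(
    strings: Sequence[str],
    v_set: Optional[GermlineSet],
    j_set: Optional[GermlineSet],
    min_anchor: int,
    max_mismatch_rate: float,
) -> list[str]:
    v_seqs = list(v_set.sequences().values()) if v_set is not None else []
    j_seqs = list(j_set.sequences().values()) if j_set is not None else []
    if v_seqs:
        cut = _batch_longest_flank(strings, v_seqs, True, min_anchor, max_mismatch_rate)
        strings = [s[c:] for s, c in zip(strings, cut)]
    if j_seqs:
        cut = _batch_longest_flank(strings, j_seqs, False, min_anchor, max_mismatch_rate)
        strings = [s[: len(s) - c] if c else s for s, c in zip(strings, cut)]
    return list(strings)


def build_cdr3_star(
    records: Sequence[CDR3Record],
    v_set: Optional[GermlineSet] = None,
    j_set: Optional[GermlineSet] = None,
    params: PreprocessParams = PreprocessParams(),
) -> ConsensusCDR3Set:
    """Full preprocessing pipeline: cluster -> consensus -> V/J trim.

    Strings that trim to empty are dropped (with a logged count); short
    strings are retained — they still count toward the set size even though
    they contribute no k-mers downstream.
    """
    if not records:
        raise ValueError("no input records")
    clusters = cluster_cdr3s(records, params.max_mismatch)
    logger.info("clustered %d records into %d clusters", len(records), len(clusters))
    consensi = [cluster_consensus(c) for c in clusters]
    provenance = [[r.id for r in c] for c in clusters]
    trimmed = _batch_trim_vj(
        consensi, v_set, j_set, params.min_anchor, params.max_mismatch_rate
    )
    strings, prov = [], []
    dropped = 0
    for s, p in zip(trimmed, provenance):
        if s:
            strings.append(s)
            prov.append(p)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d consensus strings trimmed to empty", dropped)
    logger.info("CDR3* set size: %d", len(strings))
    return ConsensusCDR3Set(strings, prov)


def read_cdr3_fasta(path: str | Path) -> list[CDR3Record]:
    """Read CDR3 records from FASTA; headers ``id|count=N`` (count defaults to 1)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        ident = rec.id
        for part in rec.description.split("|")[1:]:
            part = part.strip()
            if part.startswith("count="):
                count = int(part[len("count="):])
        records.append(CDR3Record(id=ident.split("|")[0], sequence=str(rec.seq).upper(), count=count))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_cdr3_star_fasta(cdr3_star: ConsensusCDR3Set, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s), id=f"cdr3star_{i}", description="")
        for i, s in enumerate(cdr3_star.strings)
    ]
    SeqIO.write(recs, str(path), "fasta")
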