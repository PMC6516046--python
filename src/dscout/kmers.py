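"""k-mer counting over CDR3* and classification against a germline gene set."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .germline import GermlineSet
from .preprocess import ConsensusCDR3Set

__all__ = [
    "KmerCounts",
    "KmerClass",
    "count_kmers",
    "classify_kmer",
    "is_common",
    "most_abundant_kmer",
    "common_kmer_table",
]


@dataclass
class KmerCounts:
    """Per-string presence counts: each k-mer is counted once per CDR3* string
    containing it, regardless of how many times it occurs in that string."""

    k: int
    counts: dict[str, int]
    total_strings: int


@dataclass(frozen=True)
class KmerClass:
    """Classification of a k-mer against a germline set.

    Labels are mutually exclusive with precedence
    known > mutated > trimmed > foreign:

    - ``known``: exact substring of some gene;
    - ``mutated``: one substitution away from a known k-mer;
    - ``trimmed``: contains a germline (k-2)-mer;
    - ``foreign``: none of the above.
    """

    label: str
    source_gene: Optional[str] = None


def string_kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def count_kmers(cdr3_star: ConsensusCDR3Set, k: int = 15) -> KmerCounts:
    """Count k-mers over CDR3*; strings shorter than k contribute nothing."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict[str, int] = {}
    for s in cdr3_star.strings:
        for kmer in string_kmers(s, k):
            counts[kmer] = counts.get(kmer, 0) + 1
    return KmerCounts(k=k, counts=counts, total_strings=cdr3_star.size)


def _hamming_le1(a: str, b: str) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def classify_kmer(kmer: str, genes: GermlineSet) -> KmerClass:
    k = len(kmer)
    if k < 3:
        raise ValueError("k-mer must have length >= 3")
    seqs = genes.sequences()
    for name, seq in seqs.items():
        if kmer in seq:
            return KmerClass("known", name)
    for name, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            if _hamming_le1(kmer, seq[i : i + k]):
                return KmerClass("mutated", name)
    sub_k = k - 2
    subs = string_kmers(kmer, sub_k)
    for name, seq in seqs.items():
        for i in range(len(seq) - sub_k + 1):
            if seq[i : i + sub_k] in subs:
                return KmerClass("trimmed", name)
    return KmerClass("foreign", None)


def is_common(kmer: str, counts: KmerCounts, fraction: float = 0.001) -> bool:
    """A k-mer is common iff its abundance strictly exceeds ``fraction * |CDR3*|``."""
    return counts.counts.get(kmer, 0) > fraction * counts.total_strings


def most_abundant_kmer(counts: KmerCounts) -> Optional[tuple[str, int]]:
    """Maximal-count k-mer; ties broken lexicographically.  ``None`` if empty."""
    if not counts.counts:
        return None
    return min(counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def common_kmer_table(
    counts: KmerCounts, genes: GermlineSet, fraction: float = 0.001
) -> pd.DataFrame:
    """Table of common k-mers with abundances and germline classification."""
    rows = []
    for kmer, count in counts.counts.items():
        if count > fraction * counts.total_strings:
            cls = classify_kmer(kmer, genes)
            rows.append(
                {
                    "kmer": kmer,
                    "abundance": count,
                    "label": cls.label,
                    "source_gene": cls.source_gene or "",
                }
            )
    df = pd.DataFrame(rows, columns=["kmer", "abundance", "label", "source_gene"])
    return df.sort_values(["abundance", "kmer"], ascending=[False, True]).reset_index(
        drop=True
    )
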