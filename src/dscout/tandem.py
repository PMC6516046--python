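"""Detection and analysis of CDR3s formed by two D genes (tandem D-D fusions).

A target is a tandem candidate for the ordered gene pair (D, D') when it
contains a k-mer of D ending strictly before a k-mer of D' starts.  Candidates
are decomposed into ``prefix * d_match * middle * dprime_match * suffix``,
scored against single-gene explanations with the Delta-distance filter, and
summarized as a locus-ordered matrix with its order bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .germline import GermlineSegment, GermlineSet
from .preprocess import ConsensusCDR3Set

__all__ = [
    "TandemHit",
    "TandemMatrix",
    "find_tandem_candidates",
    "decompose",
    "delta_distance",
    "classify_pseudo",
    "find_tandems",
    "tandem_matrix",
    "match_insertion_to_locus",
]


@dataclass
class TandemHit:
    """One tandem CDR3 with its five-part decomposition.

    ``prefix + d_match + middle + dprime_match + suffix`` reconstructs the
    target exactly; ``span`` is ``d_match + middle + dprime_match`` and
    ``middle`` is the inter-D insertion.
    """

    target_id: str
    target: str
    gene_d: str
    gene_dprime: str
    prefix: str
    d_match: str
    middle: str
    dprime_match: str
    suffix: str
    delta_dist: float = math.inf
    pseudo: bool = False

    def __post_init__(self) -> None:
        parts = self.prefix + self.d_match + self.middle + self.dprime_match + self.suffix
        if parts != self.target:
            raise ValueError("decomposition does not reconstruct the target")

    @property
    def span(self) -> str:
        return self.d_match + self.middle + self.dprime_match


def _gene_kmer_index(genes: GermlineSet, k: int) -> dict[str, list[tuple[str, int]]]:
    """k-mer -> [(gene name, position of the k-mer within the gene), ...]."""
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in genes.sequences().items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def _kmer_occurrences(
    target: str, index: dict[str, list[tuple[str, int]]], k: int
) -> dict[str, list[tuple[int, int]]]:
    """gene name -> [(start in target, position in gene), ...]."""
    occ: dict[str, list[tuple[int, int]]] = {}
    for i in range(len(target) - k + 1):
        owners = index.get(target[i : i + k])
        if owners:
            for name, gpos in owners:
                occ.setdefault(name, []).append((i, gpos))
    return occ


def _candidate_pairs(
    target: str, index: dict[str, list[tuple[str, int]]], k: int
) -> list[tuple[str, str]]:
    occ = _kmer_occurrences(target, index, k)
    pairs = []
    for d, occ_d in occ.items():
        for dprime, occ_dp in occ.items():
            if d != dprime:
                if min(s for s, _ in occ_d) + k <= max(s for s, _ in occ_dp):
                    pairs.append((d, dprime))
            else:
                # same-gene tandem: two ordered hits must be non-colinear —
                # a single contiguous gene block yields only hits with
                # (gene offset difference) == (target offset difference)
                if any(
                    s2 >= s1 + k and g2 - g1 < s2 - s1
                    for s1, g1 in occ_d
                    for s2, g2 in occ_d
                ):
                    pairs.append((d, d))
    return pairs


def find_tandem_candidates(
    target: str, genes: GermlineSet, k: int = 11
) -> list[tuple[str, str]]:
    """All ordered gene pairs (D, D') with a k-mer of D ending strictly before
    a k-mer of D' starts in ``target``.

    D may equal D' only via two disjoint, *non-colinear* ordered occurrences
    (two k-mers of one contiguous gene block do not make a same-gene tandem;
    the second copy must restart within the gene).  Genes with duplicate
    sequences should be collapsed beforehand.
    """
    return _candidate_pairs(target, _gene_kmer_index(genes, k), k)


def _longest_match_ending(target: str, gene: str) -> np.ndarray:
    """L[i] = length of the longest common substring of target and gene ending
    at target position i (inclusive)."""
    n, m = len(target), len(gene)
    L = np.zeros(n, dtype=int)
    prev = np.zeros(m, dtype=int)
    for i in range(n):
        cur = np.zeros(m, dtype=int)
        for j in range(m):
            if target[i] == gene[j]:
                cur[j] = (prev[j - 1] if j > 0 else 0) + 1
        L[i] = cur.max() if m else 0
        prev = cur
    return L


def decompose(target: str, d: GermlineSegment, dprime: GermlineSegment) -> TandemHit:
    """Optimal ordered five-part decomposition of a tandem candidate.

    Chooses the non-overlapping ordered pair of exact common substrings (one
    with ``d``, one with ``dprime``) maximizing ``|d_match| + |dprime_match|``;
    ties are broken toward the longer ``d_match``, then the leftmost positions.
    """
    if d.sequence is None or dprime.sequence is None:
        raise ValueError("both genes need sequences")
    n = len(target)
    L = _longest_match_ending(target, d.sequence)
    # R[j] = longest common substring of target and dprime starting at j
    R = _longest_match_ending(target[::-1], dprime.sequence[::-1])[::-1]

    best: Optional[tuple[int, int, int, int]] = None  # (sum, a, -start_d, -s)
    choice: Optional[tuple[int, int, int]] = None  # (a, end_d_exclusive, s)
    for e in range(1, n):  # d_match ends at e-1
        a = int(L[e - 1])
        if a == 0:
            continue
        for s in range(e, n):
            b = int(R[s])
            if b == 0:
                continue
            key = (a + b, a, -(e - a), -s)
            if best is None or key > best:
                best = key
                choice = (a, e, s)
    if choice is None:
        raise ValueError("no valid ordered match pair; not a tandem candidate")
    a, e, s = choice
    b = int(R[s])
    return TandemHit(
        target_id="",
        target=target,
        gene_d=d.name,
        gene_dprime=dprime.name,
        prefix=target[: e - a],
        d_match=target[e - a : e],
        middle=target[e:s],
        dprime_match=target[s : s + b],
        suffix=target[s + b :],
    )


def delta_distance(span: str, gene: GermlineSegment, delta: int = 5) -> float:
    """Minimum Hamming distance between (|span|-delta)-mers of the span and of
    the gene; ``inf`` when the gene is shorter than |span|-delta."""
    if len(span) <= delta:
        raise ValueError("span must be longer than delta")
    if gene.sequence is None:
        raise ValueError("gene needs a sequence")
    t = len(span) - delta
    g = gene.sequence
    if len(g) < t:
        return math.inf
    span_mers = np.array(
        [np.frombuffer(span[i : i + t].encode(), dtype=np.uint8) for i in range(len(span) - t + 1)]
    )
    gene_mers = np.array(
        [np.frombuffer(g[i : i + t].encode(), dtype=np.uint8) for i in range(len(g) - t + 1)]
    )
    dists = (span_mers[:, None, :] != gene_mers[None, :, :]).sum(axis=2)
    return float(dists.min())


def min_delta_distance(span: str, genes: GermlineSet, delta: int = 5) -> float:
    return min(
        (delta_distance(span, seg, delta) for seg in genes if seg.sequence is not None),
        default=math.inf,
    )


def classify_pseudo(
    hit: TandemHit, genes: GermlineSet, delta: int = 5, threshold: int = 3
) -> bool:
    """A hit is pseudo-tandem when its span is within ``threshold``
    Delta-distance of some single gene (i.e., explainable by one gene plus a
    few mutations)."""
    return min_delta_distance(hit.span, genes, delta) <= threshold


def find_tandems(
    cdr3_star: ConsensusCDR3Set,
    genes: GermlineSet,
    k: int = 11,
    delta: int = 5,
    pseudo_threshold: int = 3,
    locus_order: Optional[Sequence[str]] = None,
    ids: Optional[Sequence[str]] = None,
) -> list[TandemHit]:
    """Detect tandem CDR3s across a set, one hit (the best gene pair) per target.

    Among candidate pairs the hit maximizing ``|d_match| + |dprime_match|`` is
    reported; ties prefer the pair whose first gene is earlier in locus order.
    Every hit carries its Delta-distance to the gene set and a pseudo flag.
    """
    distinct = genes.distinct_sequences()
    order = list(locus_order) if locus_order is not None else distinct.names
    rank = {name: i for i, name in enumerate(order)}
    if ids is None:
        ids = [f"cdr3star_{i}" for i in range(cdr3_star.size)]
    index = _gene_kmer_index(distinct, k)
    hits = []
    for target_id, target in zip(ids, cdr3_star.strings):
        pairs = _candidate_pairs(target, index, k)
        best_hit = None
        best_key = None
        for d_name, dp_name in pairs:
            hit = decompose(target, distinct[d_name], distinct[dp_name])
            key = (
                -(len(hit.d_match) + len(hit.dprime_match)),
                rank.get(d_name, len(rank)),
                rank.get(dp_name, len(rank)),
            )
            if best_key is None or key < best_key:
                best_key = key
                best_hit = hit
        if best_hit is None:
            continue
        best_hit.target_id = target_id
        if len(best_hit.span) > delta:
            best_hit.delta_dist = min_delta_distance(best_hit.span, distinct, delta)
        best_hit.pseudo = best_hit.delta_dist <= pseudo_threshold
        hits.append(best_hit)
    return hits


@dataclass
class TandemMatrix:
    """Locus-ordered tandem counts with the order bias.

    Cell (i, j) counts tandem CDR3s formed by gene i then gene j.  The main
    diagonal belongs to the lower part; ``bias = n_lower / (n_upper + n_lower)``
    (``None`` when there are no hits).
    """

    order: list[str]
    counts: np.ndarray
    n_upper: int
    n_lower: int

    @property
    def bias(self) -> Optional[float]:
        total = self.n_upper + self.n_lower
        return self.n_lower / total if total else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.order, columns=self.order)


def tandem_matrix(hits: Sequence[TandemHit], order: Sequence[str]) -> TandemMatrix:
    """Count matrix over non-pseudo hits in the given locus order."""
    order = list(order)
    rank = {name: i for i, name in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for hit in hits:
        if hit.gene_d not in rank or hit.gene_dprime not in rank:
            raise ValueError(f"hit genes {hit.gene_d!r}/{hit.gene_dprime!r} not in order")
        counts[rank[hit.gene_d], rank[hit.gene_dprime]] += 1
    n_upper = int(np.triu(counts, k=1).sum())
    n_lower = int(np.tril(counts, k=0).sum())
    return TandemMatrix(order=order, counts=counts, n_upper=n_upper, n_lower=n_lower)


def match_insertion_to_locus(middle: str, locus_sequence: str) -> list[int]:
    """Start positions of exact occurrences of an inter-D insertion in a
    user-supplied locus sequence; empty for an empty insertion."""
    if not middle:
        return []
    positions = []
    start = locus_sequence.find(middle)
    while start >= 0:
        positions.append(start)
        start = locus_sequence.find(middle, start + 1)
    return positions
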