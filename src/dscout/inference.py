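"""Iterative seed-and-extend inference of D genes from the trimmed CDR3 set.

The loop: pick the most abundant k-mer as a seed, align all strings containing
it, trim the resulting motif profile by per-column information content, extend
the consensus outward while flanking columns stay conserved, report the result
as a putative gene, remove the strings it explains, and repeat until the most
abundant remaining k-mer is no longer common.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kmers import count_kmers, most_abundant_kmer, string_kmers
from .preprocess import ConsensusCDR3Set

__all__ = [
    "MotifProfile",
    "InferredSegment",
    "build_profile",
    "information_content",
    "trim_by_ic",
    "extend_consensus",
    "remove_explained",
    "infer_segments",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class MotifProfile:
    """Positional base counts for strings aligned on a seed k-mer.

    ``counts`` has one row per column of the alignment and one column per base
    (A, C, G, T); ``coverage`` is the number of strings covering each column;
    ``seed_span`` is the half-open column range occupied by the seed.
    """

    counts: np.ndarray
    coverage: np.ndarray
    seed_span: tuple[int, int]
    n_strings: int

    @property
    def frequencies(self) -> np.ndarray:
        """Per-column base frequencies (rows with zero coverage are zero)."""
        cov = self.coverage.astype(float)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(cov > 0, self.counts / cov, 0.0)
        return freq

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self, start: int, end: int) -> str:
        """Per-column plurality consensus of columns ``[start, end)``; ties go
        to the alphabetically smallest base."""
        return "".join(BASES[i] for i in np.argmax(self.counts[start:end], axis=1))


def build_profile(cdr3_star: ConsensusCDR3Set, seed: str) -> MotifProfile:
    """Align every string containing ``seed`` at its leftmost occurrence."""
    anchored: list[tuple[str, int]] = []
    for s in cdr3_star.strings:
        i = s.find(seed)
        if i >= 0:
            anchored.append((s, i))
    if not anchored:
        raise ValueError("seed does not occur in any string")
    k = len(seed)
    left = max(i for _, i in anchored)
    right = max(len(s) - i - k for s, i in anchored)
    width = left + k + right
    counts = np.zeros((width, 4), dtype=np.int64)
    coverage = np.zeros(width, dtype=np.int64)
    for s, i in anchored:
        offset = left - i
        idx = np.frombuffer(s.encode(), dtype=np.uint8)
        cols = np.arange(len(s)) + offset
        base_idx = np.empty(len(s), dtype=np.int64)
        base_idx[idx == ord("A")] = 0
        base_idx[idx == ord("C")] = 1
        base_idx[idx == ord("G")] = 2
        base_idx[idx == ord("T")] = 3
        np.add.at(counts, (cols, base_idx), 1)
        coverage[cols] += 1
    return MotifProfile(
        counts=counts,
        coverage=coverage,
        seed_span=(left, left + k),
        n_strings=len(anchored),
    )


def information_content(frequencies: np.ndarray) -> float:
    """Information content of one column in bits: ``2 + sum p log2 p``."""
    p = np.asarray(frequencies, dtype=float)
    nonzero = p[p > 0]
    return float(2.0 + np.sum(nonzero * np.log2(nonzero)))


def _column_ic(profile: MotifProfile) -> np.ndarray:
    freq = profile.frequencies
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic[profile.coverage == 0] = 0.0
    return ic


def trim_by_ic(
    profile: MotifProfile,
    ic_threshold: float = 0.5,
    min_coverage_fraction: float = 0.5,
) -> str:
    """Consensus of the maximal contiguous conserved block around the seed.

    A column is kept while its information content is >= ``ic_threshold`` and
    its coverage is at least ``min_coverage_fraction`` of the seed coverage
    (the coverage floor keeps sparsely covered flanks, whose empirical IC is
    upward-biased, from leaking into the consensus).
    """
    ic = _column_ic(profile)
    floor = min_coverage_fraction * profile.n_strings
    ok = (ic >= ic_threshold) & (profile.coverage >= floor)
    start, end = profile.seed_span
    while start > 0 and ok[start - 1]:
        start -= 1
    while end < profile.width and ok[end]:
        end += 1
    return profile.consensus(start, end)


def _extension_step(
    strings: list[str], kmer: str, before: bool, ic_threshold: float, min_support: int
) -> str | None:
    """Plurality base adjacent to ``kmer`` across strings containing it, or
    ``None`` when coverage or conservation is insufficient.

    Prefix extension anchors the leftmost occurrence of the k-mer, suffix
    extension the rightmost, so repeated k-mers cannot fold the consensus
    back onto itself.
    """
    counts = np.zeros(4, dtype=np.int64)
    k = len(kmer)
    for s in strings:
        i = s.find(kmer) if before else s.rfind(kmer)
        if i < 0:
            continue
        pos = i - 1 if before else i + k
        if 0 <= pos < len(s):
            counts[_BASE_INDEX[s[pos]]] += 1
    total = int(counts.sum())
    if total < min_support:
        return None
    if information_content(counts / total) <= ic_threshold:
        return None
    return BASES[int(np.argmax(counts))]


def extend_consensus(
    consensus: str,
    cdr3_star: ConsensusCDR3Set,
    k: int,
    ic_threshold: float = 0.5,
    min_support: int = 10,
) -> str:
    """Extend a consensus left and right while adjacent positions stay conserved.

    For the prefix: take the first k-mer of the consensus, find all strings
    containing it, and, if the position preceding the k-mer is covered by at
    least ``min_support`` strings with information content above
    ``ic_threshold``, prepend the most frequent base and iterate.  The suffix
    is extended symmetrically with the last k-mer.
    """
    if len(consensus) < k:
        raise ValueError("consensus shorter than k")
    strings = cdr3_star.strings
    for _ in range(10_000):
        base = _extension_step(strings, consensus[:k], True, ic_threshold, min_support)
        if base is None:
            break
        consensus = base + consensus
    for _ in range(10_000):
        base = _extension_step(strings, consensus[-k:], False, ic_threshold, min_support)
        if base is None:
            break
        consensus = consensus + base
    return consensus


@dataclass(frozen=True)
class InferredSegment:
    """One putative D gene reported by the inference loop."""

    sequence: str
    seed: str
    seed_abundance: int
    support: int
    iteration: int

    def __post_init__(self) -> None:
        if self.seed not in self.sequence:
            raise ValueError("seed must be a substring of the inferred sequence")


def remove_explained(
    cdr3_star: ConsensusCDR3Set, segment: InferredSegment, k: int
) -> ConsensusCDR3Set:
    """Subset of strings sharing no k-mer with the inferred segment."""
    seg_kmers = string_kmers(segment.sequence, k)
    keep = [
        i
        for i, s in enumerate(cdr3_star.strings)
        if not any(s[j : j + k] in seg_kmers for j in range(len(s) - k + 1))
    ]
    return cdr3_star.subset(keep)


def infer_segments(
    cdr3_star: ConsensusCDR3Set,
    k: int = 15,
    fraction: float = 0.001,
    ic_threshold: float = 0.5,
    min_support: int = 10,
    max_iterations: int = 1000,
) -> list[InferredSegment]:
    """The full inference loop.

    Commonness of a seed is judged against the size of the *initial* CDR3*
    set: the loop stops as soon as the most abundant remaining k-mer has
    abundance <= ``fraction * |CDR3*|``.
    """
    if cdr3_star.size == 0:
        raise ValueError("empty CDR3* set")
    threshold = fraction * cdr3_star.size
    current = cdr3_star
    segments: list[InferredSegment] = []
    for iteration in range(1, max_iterations + 1):
        counts = count_kmers(current, k)
        top = most_abundant_kmer(counts)
        if top is None:
            break
        seed, abundance = top
        if abundance <= threshold:
            break
        profile = build_profile(current, seed)
        consensus = trim_by_ic(profile, ic_threshold)
        consensus = extend_consensus(consensus, current, k, ic_threshold, min_support)
        segment = InferredSegment(
            sequence=consensus,
            seed=seed,
            seed_abundance=abundance,
            support=profile.n_strings,
            iteration=iteration,
        )
        segments.append(segment)
        logger.info(
            "iteration %d: seed %s (abundance %d) -> segment of length %d",
            iteration,
            seed,
            abundance,
            len(consensus),
        )
        remaining = remove_explained(current, segment, k)
        if remaining.size >= current.size:  # pragma: no cover - defensive
            raise RuntimeError("inference made no progress")
        current = remaining
    return segments
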