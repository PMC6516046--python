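"""Assignment of CDR3s to D genes and usage statistics.

A string is *formed by* gene D when it contains a k-mer of D and no k-mer of
any other gene in the (duplicate-collapsed) set; such strings are *traceable*.
Usage of D is the fraction of traceable strings formed by D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .germline import GermlineSet
from .kmers import string_kmers
from .preprocess import ConsensusCDR3Set

__all__ = ["UsageTable", "formed_by", "usage_table", "allele_usage"]

logger = logging.getLogger(__name__)


def _gene_kmer_index(genes: GermlineSet, k: int) -> dict[str, set[str]]:
    """k-mer -> set of gene names owning it, over distinct gene sequences."""
    index: dict[str, set[str]] = {}
    for name, seq in genes.sequences().items():
        for kmer in string_kmers(seq, k):
            index.setdefault(kmer, set()).add(name)
    return index


def _genes_hit(target: str, index: dict[str, set[str]], k: int) -> set[str]:
    hit: set[str] = set()
    for i in range(len(target) - k + 1):
        owners = index.get(target[i : i + k])
        if owners:
            hit.update(owners)
    return hit


def formed_by(target: str, genes: GermlineSet, k: int = 11) -> Optional[str]:
    """The unique gene whose k-mers occur in ``target``, or ``None``.

    Duplicate gene sequences are collapsed first, so that identical genes do
    not make every containing string ambiguous.
    """
    distinct = genes.distinct_sequences()
    hit = _genes_hit(target, _gene_kmer_index(distinct, k), k)
    if len(hit) == 1:
        return hit.pop()
    return None


@dataclass
class UsageTable:
    """Per-gene usage over traceable strings."""

    usage: dict[str, float]
    counts: dict[str, int]
    traceable_count: int
    total: int

    @property
    def traceable_fraction(self) -> float:
        return self.traceable_count / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "count": self.counts[g], "usage": self.usage[g]}
            for g in sorted(self.usage, key=lambda g: -self.counts[g])
        ]
        return pd.DataFrame(rows, columns=["gene", "count", "usage"])


def usage_table(
    cdr3_star: ConsensusCDR3Set, genes: GermlineSet, k: int = 11
) -> UsageTable:
    """Usage of each gene: traceable strings formed by it / all traceable strings."""
    if cdr3_star.size == 0:
        raise ValueError("empty CDR3* set")
    distinct = genes.distinct_sequences()
    index = _gene_kmer_index(distinct, k)
    counts = {name: 0 for name in distinct.names}
    traceable = 0
    for s in cdr3_star.strings:
        hit = _genes_hit(s, index, k)
        if len(hit) == 1:
            counts[hit.pop()] += 1
            traceable += 1
    if traceable == 0:
        logger.warning("no traceable strings; all usages reported as 0")
        usage = {name: 0.0 for name in counts}
    else:
        usage = {name: c / traceable for name, c in counts.items()}
    return UsageTable(
        usage=usage, counts=counts, traceable_count=traceable, total=cdr3_star.size
    )


@dataclass
class AlleleUsage:
    """Within one allele group: resolved counts per variant plus unresolved."""

    group: str
    counts: dict[str, int]
    unresolved: int

    @property
    def percentages(self) -> dict[str, float]:
        resolved = sum(self.counts.values())
        if resolved == 0:
            return {v: 0.0 for v in self.counts}
        return {v: 100.0 * c / resolved for v, c in self.counts.items()}


def allele_usage(
    cdr3_star: ConsensusCDR3Set, genes: GermlineSet, k: int = 11
) -> dict[str, AlleleUsage]:
    """Per-allele-group usage split.

    A string assigned to an allele group (it contains k-mers of exactly one
    group) is attributed to the variant owning a k-mer that is unique among
    that group's variants; strings matching no variant-unique k-mer count as
    unresolved.  Only groups with >= 2 variants are reported.
    """
    groups: dict[str, list] = {}
    for seg in genes:
        if seg.sequence is not None:
            groups.setdefault(seg.allele_group, []).append(seg)
    multi = {g: segs for g, segs in groups.items() if len(segs) >= 2}

    # group-level ownership: k-mer -> groups containing it
    group_index: dict[str, set[str]] = {}
    for seg in genes:
        if seg.sequence is None:
            continue
        for kmer in string_kmers(seg.sequence, k):
            group_index.setdefault(kmer, set()).add(seg.allele_group)

    # variant-unique k-mers within each multi-variant group
    variant_unique: dict[str, dict[str, set[str]]] = {}
    for gname, segs in multi.items():
        owner: dict[str, set[str]] = {}
        for seg in segs:
            for kmer in string_kmers(seg.sequence, k):
                owner.setdefault(kmer, set()).add(seg.name)
        variant_unique[gname] = {seg.name: set() for seg in segs}
        for kmer, variants in owner.items():
            if len(variants) == 1:
                variant_unique[gname][next(iter(variants))].add(kmer)

    result = {
        gname: AlleleUsage(
            group=gname, counts={seg.name: 0 for seg in segs}, unresolved=0
        )
        for gname, segs in multi.items()
    }
    for s in cdr3_star.strings:
        hit_groups = _genes_hit(s, group_index, k)
        if len(hit_groups) != 1:
            continue
        gname = hit_groups.pop()
        if gname not in multi:
            continue
        kmers = string_kmers(s, k)
        matched = [
            variant
            for variant, uniq in variant_unique[gname].items()
            if kmers & uniq
        ]
        if len(matched) == 1:
            result[gname].counts[matched[0]] += 1
        else:
            result[gname].unresolved += 1
    return result
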