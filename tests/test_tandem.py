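import itertools
import math

import pytest

from dscout.germline import GermlineSegment, GermlineSet
from dscout.preprocess import ConsensusCDR3Set
from dscout.simulate import SimulationConfig, simulate_repertoire
from dscout.tandem import (
    TandemHit,
    classify_pseudo,
    decompose,
    delta_distance,
    find_tandem_candidates,
    find_tandems,
    match_insertion_to_locus,
    tandem_matrix,
)

from conftest import random_seq

GA = "GTATTAGGATTTTTGGAGTGGTTATCAA"
GB = "GTGGATACAGCTATGGTTCGGGGAGTTA"


@pytest.fixture
def pair_genes():
    return GermlineSet(
        [GermlineSegment("GA", GA), GermlineSegment("GB", GB)], kind="D"
    )


def oracle_decompose(target, d_seq, dp_seq):
    """Exhaustive all-substring-pairs oracle with the documented tie-breaking:
    max |A|+|B|, then max |A|, then leftmost A, then leftmost B."""
    best_key, best = None, None
    n = len(target)
    for i in range(n):
        for a in range(1, n - i + 1):
            A = target[i : i + a]
            if A not in d_seq:
                continue
            for s in range(i + a, n):
                for b in range(1, n - s + 1):
                    B = target[s : s + b]
                    if B not in dp_seq:
                        continue
                    key = (a + b, a, -i, -s)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = (i, a, s, b)
    return best


def oracle_delta(span, gene_seq, delta):
    t = len(span) - delta
    if len(gene_seq) < t:
        return math.inf
    best = math.inf
    for i in range(len(span) - t + 1):
        for j in range(len(gene_seq) - t + 1):
            d = sum(x != y for x, y in zip(span[i : i + t], gene_seq[j : j + t]))
            best = min(best, d)
    return best


class TestCandidates:
    def test_ordered_pair_found(self, pair_genes):
        target = GA[:11] + "CAG" + GB[:11]
        assert find_tandem_candidates(target, pair_genes) == [("GA", "GB")]

    def test_single_block_no_candidates(self, pair_genes):
        assert find_tandem_candidates("TT" + GA[:14] + "AA", pair_genes) == []

    def test_reverse_order_detected_as_reverse(self, pair_genes):
        target = GB[:11] + "CAG" + GA[:11]
        assert find_tandem_candidates(target, pair_genes) == [("GB", "GA")]

    def test_same_gene_needs_two_disjoint_hits(self, pair_genes):
        assert ("GA", "GA") in find_tandem_candidates(
            GA[:11] + "CCC" + GA[:11], pair_genes
        )
        assert ("GA", "GA") not in find_tandem_candidates(
            "T" + GA[:12] + "T", pair_genes
        )

    def test_positional_scan_oracle(self, rng, pair_genes):
        # brute-force check of the ordering rule on random composites
        for _ in range(50):
            pieces = [
                random_seq(rng, 4),
                GA[:11] if rng.random() < 0.7 else random_seq(rng, 11),
                random_seq(rng, 3),
                GB[:11] if rng.random() < 0.7 else random_seq(rng, 11),
                random_seq(rng, 4),
            ]
            target = "".join(pieces)
            pairs = set(find_tandem_candidates(target, pair_genes, k=11))
            k = 11
            starts = {}
            for name, seq in (("GA", GA), ("GB", GB)):
                pos = [
                    i
                    for i in range(len(target) - k + 1)
                    if target[i : i + k] in {seq[j : j + k] for j in range(len(seq) - k + 1)}
                ]
                if pos:
                    starts[name] = pos
            expected = {
                (d, dp)
                for d, dp in itertools.product(starts, repeat=2)
                if min(starts[d]) + k <= max(starts[dp])
            }
            assert pairs == expected


class TestDecompose:
    def test_constructed_example(self):
        d = GermlineSegment("d", "AAAACCCC")
        dp = GermlineSegment("dp", "GGGGTTTT")
        hit = decompose("TT" + "AAAACCCC" + "CAG" + "GGGGTTTT" + "A", d, dp)
        assert (hit.prefix, hit.d_match, hit.middle, hit.dprime_match, hit.suffix) == (
            "TT",
            "AAAACCCC",
            "CAG",
            "GGGGTTTT",
            "A",
        )
        assert hit.span == "AAAACCCC" + "CAG" + "GGGGTTTT"

    def test_published_style_middle_length(self):
        # d_match 25 nt, inter-D insertion 6 nt, dprime_match 16 nt
        d_match = "GTATTAGGATTTTTGGAGTGGTTAT"
        dprime_match = "GTGGATACAGCTATGG"
        target = "GC" + d_match + "CAGCCA" + dprime_match + "TA"
        hit = decompose(
            target,
            GermlineSegment("d", d_match),
            GermlineSegment("dp", dprime_match + "TTCGGG"),
        )
        assert hit.middle == "CAGCCA"
        assert len(hit.middle) == 6

    def test_abutting_matches_empty_middle(self):
        d = GermlineSegment("d", "AAAACCCC")
        dp = GermlineSegment("dp", "GGGGTTTT")
        hit = decompose("AAAACCCCGGGGTTTT", d, dp)
        assert hit.middle == ""

    def test_concatenation_identity(self, rng):
        for _ in range(100):
            d = GermlineSegment("d", random_seq(rng, 14))
            dp = GermlineSegment("dp", random_seq(rng, 14))
            target = (
                random_seq(rng, 3)
                + d.sequence[2:11]
                + random_seq(rng, 4)
                + dp.sequence[1:10]
                + random_seq(rng, 3)
            )
            hit = decompose(target, d, dp)
            assert (
                hit.prefix + hit.d_match + hit.middle + hit.dprime_match + hit.suffix
                == target
            )

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(150):
            d = GermlineSegment("d", random_seq(rng, 10))
            dp = GermlineSegment("dp", random_seq(rng, 10))
            target = (
                random_seq(rng, 2)
                + d.sequence[rng.integers(0, 4) :]
                + random_seq(rng, int(rng.integers(0, 4)))
                + dp.sequence[: 10 - rng.integers(0, 4)]
                + random_seq(rng, 2)
            )
            oracle = oracle_decompose(target, d.sequence, dp.sequence)
            if oracle is None:
                with pytest.raises(ValueError):
                    decompose(target, d, dp)
                continue
            i, a, s, b = oracle
            hit = decompose(target, d, dp)
            assert (len(hit.prefix), len(hit.d_match)) == (i, a)
            assert (len(hit.prefix) + len(hit.d_match) + len(hit.middle), len(hit.dprime_match)) == (s, b)

    def test_no_valid_pair_rejected(self):
        with pytest.raises(ValueError):
            decompose("AAAA", GermlineSegment("d", "CCCC"), GermlineSegment("dp", "GGGG"))


class TestDeltaDistance:
    def test_shared_tmer_gives_zero(self):
        # t = 9 - 5 = 4; ACGT occurs in both
        assert delta_distance("ACGTACGTA", GermlineSegment("g", "TTTTACGTTT")) == 0

    def test_substring_gives_zero(self):
        gene = GermlineSegment("g", "AAACGTACGTAAA")
        for delta in (1, 3, 5):
            assert delta_distance("ACGTACGTA", gene, delta=delta) == 0

    def test_brute_force_value(self):
        assert delta_distance("ACGTACGTA", GermlineSegment("g", "CCCCCCCCCC")) == 3

    def test_gene_shorter_than_t_skipped(self):
        assert delta_distance("ACGTACGTAA", GermlineSegment("g", "ACG")) == math.inf

    def test_span_not_longer_than_delta_rejected(self):
        with pytest.raises(ValueError):
            delta_distance("ACGTA", GermlineSegment("g", "ACGTACGT"), delta=5)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            span = random_seq(rng, int(rng.integers(8, 16)))
            gene = GermlineSegment("g", random_seq(rng, int(rng.integers(4, 20))))
            assert delta_distance(span, gene) == oracle_delta(span, gene.sequence, 5)


def make_hit(target, prefix, d_match, middle, dprime_match, suffix):
    return TandemHit(
        target_id="t",
        target=target,
        gene_d="GA",
        gene_dprime="GB",
        prefix=prefix,
        d_match=d_match,
        middle=middle,
        dprime_match=dprime_match,
        suffix=suffix,
    )


class TestClassifyPseudo:
    def test_span_inside_one_gene_is_pseudo(self, pair_genes):
        span = GA[2:26]
        hit = make_hit("TT" + span + "AA", "TT", span[:12], "", span[12:], "AA")
        assert classify_pseudo(hit, pair_genes) is True

    def test_three_mutations_still_pseudo(self, rng, pair_genes):
        span = list(GA[1:27])
        for pos in (4, 12, 20):
            span[pos] = "ACGT"[(("ACGT".index(span[pos])) + 1) % 4]
        span = "".join(span)
        hit = make_hit(span, "", span[:13], "", span[13:], "")
        assert classify_pseudo(hit, pair_genes) is True

    def test_true_composite_not_pseudo(self, rng, pair_genes):
        span = GA[:13] + random_seq(rng, 20) + GB[-13:]
        hit = make_hit(span, "", GA[:13], random_seq(rng, 0) + span[13:-13], span[-13:], "")
        assert classify_pseudo(hit, pair_genes) is False

    def test_decomposition_must_reconstruct(self):
        with pytest.raises(ValueError):
            make_hit("AAAA", "A", "A", "A", "A", "A")


class TestTandemMatrix:
    def test_bias_arithmetic(self):
        order = [f"g{i}" for i in range(4)]
        hits = []
        for d, dp in [("g0", "g1")] * 5 + [("g1", "g3")] * 4 + [("g2", "g2")]:
            target = "AAAACCCCGGGGTTTT"
            hits.append(
                TandemHit("t", target, d, dp, "", "AAAACCCC", "", "GGGGTTTT", "")
            )
        m = tandem_matrix(hits, order)
        assert m.n_upper == 9
        assert m.n_lower == 1  # diagonal belongs to the lower part
        assert m.bias == pytest.approx(0.1)

    def test_all_upper_bias_zero(self):
        hits = [
            TandemHit("t", "ACGTACGT", "g0", "g1", "", "ACGT", "", "ACGT", "")
        ]
        m = tandem_matrix(hits, ["g0", "g1"])
        assert m.bias == 0.0

    def test_zero_hits_bias_na(self):
        m = tandem_matrix([], ["g0", "g1"])
        assert m.bias is None

    def test_random_hits_against_count_oracle(self, rng):
        order = [f"g{i}" for i in range(5)]
        hits = []
        n_upper = n_lower = 0
        for _ in range(50):
            i, j = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            if i < j:
                n_upper += 1
            else:
                n_lower += 1
            hits.append(
                TandemHit("t", "ACGTACGT", order[i], order[j], "", "ACGT", "", "ACGT", "")
            )
        m = tandem_matrix(hits, order)
        assert (m.n_upper, m.n_lower) == (n_upper, n_lower)
        assert int(m.counts.sum()) == 50

    def test_unknown_gene_rejected(self):
        hit = TandemHit("t", "ACGTACGT", "zz", "g1", "", "ACGT", "", "ACGT", "")
        with pytest.raises(ValueError):
            tandem_matrix([hit], ["g0", "g1"])


class TestMatchInsertion:
    def test_planted_offset_found(self, rng):
        locus = random_seq(rng, 500)
        middle = locus[137:167]
        assert 137 in match_insertion_to_locus(middle, locus)

    def test_random_middle_not_found(self, rng):
        locus = random_seq(rng, 500)
        assert match_insertion_to_locus(random_seq(rng, 25), locus) == []

    def test_empty_middle_guarded(self, rng):
        assert match_insertion_to_locus("", random_seq(rng, 100)) == []


@pytest.fixture(scope="module")
def sim_hits():
    import numpy as np

    rng = np.random.default_rng(77)
    genes_list = [(f"g{i}", random_seq(rng, 28)) for i in range(6)]
    config = SimulationConfig(d_genes=genes_list, n_cdr3=20_000, tandem_rate=0.01, seed=21)
    records, truth = simulate_repertoire(config)
    star = ConsensusCDR3Set([r.sequence for r in records])
    genes = GermlineSet([GermlineSegment(n, s) for n, s in config.d_genes], kind="D")
    hits = find_tandems(star, genes, ids=[r.id for r in records])
    return config, truth, hits


class TestFindTandemsOnSimulation:
    def test_concatenation_identity_on_all_hits(self, sim_hits):
        _, _, hits = sim_hits
        for hit in hits:
            assert (
                hit.prefix + hit.d_match + hit.middle + hit.dprime_match + hit.suffix
                == hit.target
            )

    def test_sensitivity_on_well_supported_events(self, sim_hits):
        config, truth, hits = sim_hits
        hit_by_id = {h.target_id: h for h in hits}
        eligible = detected = 0
        for t in truth:
            if not t.is_tandem:
                continue
            if min(len(d) for d in t.d_substrings) < 11:
                continue  # both retained gene parts must span a k-mer
            eligible += 1
            h = hit_by_id.get(t.cdr3_id.split("_")[0] + "_c0")
            h = hit_by_id.get(t.cdr3_id, h)
            if h is not None and not h.pseudo:
                if (h.gene_d, h.gene_dprime) == t.source_genes:
                    detected += 1
        assert eligible > 50
        assert detected / eligible >= 0.95

    def test_bias_low_without_reversed_events(self, sim_hits):
        config, _, hits = sim_hits
        order = [n for n, _ in config.d_genes]
        m = tandem_matrix([h for h in hits if not h.pseudo], order)
        assert m.n_upper + m.n_lower > 50
        assert m.bias <= 0.01
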