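import numpy as np
import pytest

from conftest import random_dna
from oracles import mst_weight_bruteforce
from sexsatkit.abundance import reverse_complement
from sexsatkit.haplotypes import (
    HaplotypeNode,
    Monomer,
    build_mst,
    extract_monomers,
    filter_singletons,
    group_stats,
    hamming,
)
from sexsatkit.synthetic import _build_array


def _nodes_from(seqs, totals=None):
    totals = totals or [2] * len(seqs)
    return [
        HaplotypeNode(sequence=s, counts={"lib": t}, total=t)
        for s, t in zip(seqs, totals)
    ]


class TestExtractMonomers:
    def test_exact_concatemers_yield_consensus(self, rng):
        consensus = random_dna(rng, 28)
        array = consensus * 8
        reads = [array[k:k + 150] for k in range(0, 60, 7)]  # every phase offset
        monomers = extract_monomers(reads, consensus, library="m")
        assert len(monomers) == len(reads)
        assert all(m.sequence == consensus for m in monomers)

    def test_strand_invariance(self, rng):
        consensus = random_dna(rng, 28)
        read = (consensus * 7)[5:155]
        fwd = extract_monomers([read], consensus)
        rev = extract_monomers([reverse_complement(read)], consensus)
        assert [m.sequence for m in fwd] == [m.sequence for m in rev]

    def test_output_length_is_always_rul(self, rng):
        consensus = random_dna(rng, 28)
        variant = list(consensus)
        variant[3] = "A" if consensus[3] != "A" else "C"
        array = consensus * 4 + "".join(variant) * 4
        reads = [array[int(i):int(i) + 150] for i in rng.integers(0, len(array) - 150, 30)]
        for m in extract_monomers(reads, consensus):
            assert len(m.sequence) == 28

    def test_read_below_identity_floor_contributes_nothing(self, rng):
        consensus = random_dna(rng, 28)
        assert extract_monomers([random_dna(rng, 150)], consensus) == []

    def test_repeat_unit_longer_than_reads_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_monomers([random_dna(rng, 50)], random_dna(rng, 60))

    def test_variant_copy_ratio_recovered(self, rng):
        """Two variants planted at a 10:1 copy ratio come back ~10:1."""
        v1 = random_dna(rng, 28)
        v2 = list(v1)
        v2[5] = "A" if v1[5] != "A" else "T"
        v2 = "".join(v2)
        array = _build_array(rng, {v1: 200, v2: 20}, 200)
        starts = rng.integers(0, len(array) - 150, 400)
        reads = [array[s:s + 150] for s in starts]
        counts = {v1: 0, v2: 0}
        for m in extract_monomers(reads, v1):
            if m.sequence in counts:
                counts[m.sequence] += 1
        assert counts[v2] > 0
        assert 6.0 < counts[v1] / counts[v2] < 16.0

    def test_all_copies_mode_returns_every_complete_copy(self, rng):
        consensus = random_dna(rng, 28)
        read = (consensus * 7)[0:150]  # 5 complete copies
        monomers = extract_monomers([read], consensus, all_copies=True)
        assert len(monomers) == 5


class TestFilterSingletons:
    def test_singleton_removed(self):
        monomers = [Monomer("AAAA", "m")] * 5 + [Monomer("AAAT", "m")]
        nodes = filter_singletons(monomers)
        assert len(nodes) == 1
        assert nodes[0].sequence == "AAAA" and nodes[0].total == 5

    def test_all_distinct_gives_empty_set(self, rng):
        monomers = [Monomer(random_dna(rng, 20), "m") for _ in range(10)]
        assert filter_singletons(monomers) == []

    def test_per_library_counts_retained(self):
        monomers = [Monomer("AAAA", "m")] * 3 + [Monomer("AAAA", "f")] * 2
        node = filter_singletons(monomers)[0]
        assert node.counts == {"m": 3, "f": 2} and node.total == 5

    def test_counts_conserved_and_never_increased(self, rng):
        seqs = [random_dna(rng, 12) for _ in range(5)]
        monomers = [
            Monomer(seqs[int(i)], ["m", "f"][int(j)])
            for i, j in zip(rng.integers(0, 5, 60), rng.integers(0, 2, 60))
        ]
        nodes = filter_singletons(monomers)
        assert sum(n.total for n in nodes) <= len(monomers)
        for n in nodes:
            assert n.total == sum(n.counts.values()) >= 2


class TestBuildMST:
    def test_single_node_has_no_edges(self):
        g = build_mst(_nodes_from(["ACGT"]))
        assert g.edges == [] and g.is_spanning_tree

    def test_three_haplotype_chain(self):
        # mutual Hamming distances (1, 1, 2): the two distance-1 edges win
        g = build_mst(_nodes_from(["AAAA", "AAAT", "AATT"]))
        assert g.total_weight == 2
        assert sorted(w for _, _, w in g.edges) == [1, 1]

    def test_seven_random_haplotypes_match_bruteforce(self, rng):
        seqs = list({random_dna(rng, 28) for _ in range(7)})
        nodes = _nodes_from(seqs)
        dist = [[hamming(a.sequence, b.sequence) for b in nodes] for a in nodes]
        assert build_mst(nodes).total_weight == mst_weight_bruteforce(dist)

    def test_tree_shape_and_determinism(self, rng):
        seqs = list({random_dna(rng, 16) for _ in range(6)})
        nodes = _nodes_from(seqs, totals=list(rng.integers(2, 30, len(seqs))))
        g1, g2 = build_mst(nodes), build_mst(nodes)
        assert g1.edges == g2.edges
        assert len(g1.edges) == len(nodes) - 1

    def test_unequal_lengths_need_explicit_flag(self):
        nodes = _nodes_from(["AAAA", "AAAAA"])
        with pytest.raises(ValueError):
            build_mst(nodes)
        g = build_mst(nodes, allow_unequal=True)
        assert g.total_weight == 1  # single insertion

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_mst([])


class TestGroupStats:
    def _graph(self, nodes):
        return build_mst(nodes)

    def test_fully_shared_haplotypes_have_no_exclusives(self):
        nodes = [
            HaplotypeNode("AAAA", {"m": 2, "f": 3}, 5),
            HaplotypeNode("AAAT", {"m": 1, "f": 1}, 2),
        ]
        stats = group_stats(self._graph(nodes), {"m": "M", "f": "F"})
        assert stats["exclusive"] == {"F": 0, "M": 0}
        assert stats["shared_all_groups"] == 2

    def test_planted_exclusive_counts(self):
        nodes = [HaplotypeNode(f"AAA{b}", {"m": 2}, 2) for b in "ACGTT"[:4]]
        nodes += [HaplotypeNode("CCCC", {"m": 1, "f": 3}, 4)]
        stats = group_stats(self._graph(nodes), {"m": "M", "f": "F"})
        assert stats["exclusive"]["M"] == 4
        assert stats["exclusive"]["F"] == 0

    def test_categories_partition_the_node_set(self, rng):
        libs = ["a", "b", "c"]
        nodes = []
        seqs = list({random_dna(rng, 10) for _ in range(12)})
        for seq in seqs:
            counts = {
                lib: int(c)
                for lib, c in zip(libs, rng.integers(0, 3, 3))
            }
            counts = {k: v for k, v in counts.items() if v > 0} or {"a": 2}
            nodes.append(HaplotypeNode(seq, counts, sum(counts.values())))
        stats = group_stats(self._graph(nodes), {lib: lib.upper() for lib in libs})
        total = (
            sum(stats["exclusive"].values())
            + stats["shared_all_groups"]
            + stats["shared_partial"]
        )
        assert total == stats["total_haplotypes"] == len(nodes)

    def test_unmapped_library_is_an_error(self):
        nodes = [HaplotypeNode("AAAA", {"m": 2}, 2)]
        with pytest.raises(KeyError):
            group_stats(self._graph(nodes), {"other": "X"})

    def test_tuple_groups_accepted(self):
        nodes = [HaplotypeNode("AAAA", {"karF_male": 2}, 2)]
        stats = group_stats(self._graph(nodes), {"karF_male": ("KarF", "M")})
        assert stats["exclusive"] == {"KarF_M": 1}
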