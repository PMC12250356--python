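"""Monomer-haplotype analysis of a satDNA family across read libraries.

From each read that aligns well enough to the family consensus, exactly one
complete, gap-free monomer copy is excised in the consensus frame (the
best-aligned copy in the read). Identical monomers form a haplotype;
haplotypes seen only once across all libraries (singletons) are discarded
as likely sequencing errors. The surviving haplotypes are connected by a
minimum spanning tree over pairwise Hamming distances, whose edge weights
are nucleotide mutational steps — the classic haplotype-network view used
to ask whether particular variants are private to one karyomorph or sex
(e.g. Y-chromosome-restricted clusters appear as male-exclusive branches).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .abundance import reverse_complement


@dataclass
class Monomer:
    sequence: str
    source_library: str


@dataclass
class HaplotypeNode:
    sequence: str
    counts: dict[str, int]
    total: int


@dataclass
class HaplotypeGraph:
    nodes: list[HaplotypeNode]
    edges: list[tuple[int, int, int]]  # (node index, node index, mutational steps)
    is_spanning_tree: bool = True

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


# ---------------------------------------------------------------------------
# Monomer extraction


class _PhaseScanner:
    """Ungapped phase scan of reads against a tiled consensus.

    Monomer excision treats a read as an ungapped window onto the tandem
    array, so the right alignment model is a pure substitution one: for
    every rotation phase of the consensus (and both read strands) compare
    the read against the consensus tiled from that phase, and keep the
    phase with the fewest mismatches. This sidesteps the degenerate
    gapped/ungapped ties an edit-distance aligner can return for
    substitution-only divergence.
    """

    def __init__(self, consensus: str) -> None:
        self.consensus = consensus
        self.rul = len(consensus)
        self._tiles: np.ndarray | None = None
        self._tile_len = 0

    def _tiles_for(self, length: int) -> np.ndarray:
        if self._tiles is None or self._tile_len < length:
            reps = -(-(length + self.rul) // self.rul) + 1
            track = np.frombuffer((self.consensus * reps).encode(), dtype="S1")
            self._tiles = np.stack([track[p:p + length] for p in range(self.rul)])
            self._tile_len = length
        return self._tiles[:, :length]

    def best_phase(self, read: str) -> tuple[str, int, int]:
        """Return (oriented read, phase, mismatches) over both strands.

        ``phase`` p means read position i sits at consensus position
        (p + i) mod rul. Ties prefer the forward strand, then the smaller
        phase.
        """
        best = None
        for oriented in (read, reverse_complement(read)):
            arr = np.frombuffer(oriented.encode(), dtype="S1")
            tiles = self._tiles_for(arr.size)
            mismatches = (tiles != arr).sum(axis=1)
            p = int(mismatches.argmin())
            if best is None or mismatches[p] < best[2]:
                best = (oriented, p, int(mismatches[p]))
        return best


def _best_monomer(read: str, scanner: _PhaseScanner, min_identity: float,
                  all_copies: bool = False) -> list[str]:
    rul = scanner.rul
    oriented, phase, mismatches = scanner.best_phase(read)
    if 100.0 * (len(read) - mismatches) / len(read) < min_identity:
        return []
    first = (rul - phase) % rul  # first read position at consensus frame 0
    candidates: list[tuple[int, int, str]] = []  # (-window matches, qstart, monomer)
    for q in range(first, len(oriented) - rul + 1, rul):
        window = oriented[q:q + rul]
        win_matches = sum(
            a == b and a != "N" for a, b in zip(window, scanner.consensus)
        )
        candidates.append((-win_matches, q, window))
    if not candidates:
        return []
    candidates.sort()
    if all_copies:
        return [c[2] for c in candidates]
    return [candidates[0][2]]


def extract_monomers(
    reads: Sequence[str],
    sat_consensus: str,
    library: str = "library",
    min_identity: float = 80.0,
    subsample: int | None = None,
    seed: int = 0,
    all_copies: bool = False,
) -> list[Monomer]:
    """Excise one complete monomer copy per qualifying read, consensus frame.

    Reads shorter than the repeat unit are invalid. Extraction is strand-
    aware: a reverse-complement read yields the same forward-phase monomer
    as its forward twin. With ``all_copies`` every complete copy in the
    read is returned instead of only the best-aligned one.
    """
    if not reads:
        return []
    rul = len(sat_consensus)
    if rul > max(len(r) for r in reads):
        raise ValueError(f"repeat unit ({rul} bp) longer than the reads")
    if subsample is not None and subsample < len(reads):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(reads), size=subsample, replace=False)
        reads = [reads[i] for i in sorted(idx)]
    scanner = _PhaseScanner(sat_consensus)
    out = []
    for read in reads:
        if len(read) < rul:
            continue
        for mono in _best_monomer(read, scanner, min_identity, all_copies):
            out.append(Monomer(sequence=mono, source_library=library))
    return out


# ---------------------------------------------------------------------------
# Haplotype collapsing


def filter_singletons(monomers: Sequence[Monomer]) -> list[HaplotypeNode]:
    """Collapse monomers into exact-sequence haplotypes, dropping singletons.

    A haplotype is an exact sequence equivalence class; classes whose total
    count across all libraries is 1 are removed as putative sequencing
    errors. Nodes are ordered by decreasing total, then sequence.
    """
    by_seq: dict[str, dict[str, int]] = {}
    for mono in monomers:
        by_seq.setdefault(mono.sequence, {})
        lib_counts = by_seq[mono.sequence]
        lib_counts[mono.source_library] = lib_counts.get(mono.source_library, 0) + 1
    nodes = []
    for seq, counts in by_seq.items():
        total = sum(counts.values())
        if total >= 2:
            nodes.append(HaplotypeNode(sequence=seq, counts=dict(counts), total=total))
    nodes.sort(key=lambda nd: (-nd.total, nd.sequence))
    return nodes


# ---------------------------------------------------------------------------
# Minimum spanning tree


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance needs equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def _pairwise_distances(nodes: list[HaplotypeNode], allow_unequal: bool) -> np.ndarray:
    n = len(nodes)
    lengths = {len(nd.sequence) for nd in nodes}
    if len(lengths) > 1 and not allow_unequal:
        raise ValueError(
            "haplotype sequences differ in length; pass allow_unequal=True "
            "for edit-distance mode"
        )
    dist = np.zeros((n, n), dtype=int)
    if len(lengths) == 1:
        arr = np.frombuffer(
            "".join(nd.sequence for nd in nodes).encode(), dtype="S1"
        ).reshape(n, lengths.pop())
        for i in range(n):
            dist[i] = (arr != arr[i]).sum(axis=1)
    else:
        import edlib

        for i in range(n):
            for j in range(i + 1, n):
                d = edlib.align(nodes[i].sequence, nodes[j].sequence, mode="NW")["editDistance"]
                dist[i, j] = dist[j, i] = d
    return dist


def build_mst(nodes: list[HaplotypeNode], allow_unequal: bool = False) -> HaplotypeGraph:
    """Minimum spanning tree over the complete mutational-step graph.

    Kruskal with a deterministic tie-break: among equal-weight edges, the
    one joining the higher combined haplotype totals wins, then lexicographic
    endpoint order. Tie-breaking can change topology but never total weight.
    """
    if not nodes:
        raise ValueError("need at least one haplotype node")
    n = len(nodes)
    if n == 1:
        return HaplotypeGraph(nodes=list(nodes), edges=[], is_spanning_tree=True)
    dist = _pairwise_distances(list(nodes), allow_unequal)

    def edge_key(i: int, j: int):
        si, sj = sorted((nodes[i].sequence, nodes[j].sequence))
        return (int(dist[i, j]), -(nodes[i].total + nodes[j].total), si, sj)

    candidates = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda ij: edge_key(*ij),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for i, j in candidates:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, int(dist[i, j])))
            if len(edges) == n - 1:
                break
    return HaplotypeGraph(nodes=list(nodes), edges=edges, is_spanning_tree=True)


def to_networkx(graph: HaplotypeGraph):
    """Export as a networkx graph (for GraphML / visualization tools)."""
    import networkx as nx

    g = nx.Graph()
    for idx, nd in enumerate(graph.nodes):
        g.add_node(idx, sequence=nd.sequence, total=nd.total,
                   **{f"count_{lib}": c for lib, c in sorted(nd.counts.items())})
    for i, j, w in graph.edges:
        g.add_edge(i, j, steps=w)
    return g


# ---------------------------------------------------------------------------
# Group sharing / exclusivity


def group_stats(
    graph: HaplotypeGraph,
    groups: Mapping[str, str | tuple],
    top_k: int = 3,
) -> dict:
    """Per-group exclusivity and sharing summary over the haplotype set.

    ``groups`` maps each library label to a group (e.g. ``(karyomorph,
    sex)`` or a plain label). A haplotype is *exclusive* to a group when
    its counts are nonzero in exactly one group; *shared (all)* when present
    in every group; the remainder is *shared (partial)*. The three
    categories partition the haplotype set. ``major_shared`` lists the
    ``top_k`` highest-count haplotypes present in all groups.
    """

    def norm(g) -> str:
        return "_".join(map(str, g)) if isinstance(g, tuple) else str(g)

    group_of = {lib: norm(g) for lib, g in groups.items()}
    all_groups = sorted(set(group_of.values()))
    exclusive = {g: 0 for g in all_groups}
    shared_all = shared_partial = 0
    major = []
    for nd in graph.nodes:
        for lib in nd.counts:
            if lib not in group_of:
                raise KeyError(f"library {lib!r} has no group assignment")
        present = sorted({group_of[lib] for lib, c in nd.counts.items() if c > 0})
        if len(present) == 1:
            exclusive[present[0]] += 1
        elif len(present) == len(all_groups):
            shared_all += 1
            major.append(nd)
        else:
            shared_partial += 1
    major.sort(key=lambda nd: (-nd.total, nd.sequence))
    total = len(graph.nodes)
    summary = {
        "total_haplotypes": total,
        "exclusive": exclusive,
        "shared_all_groups": shared_all,
        "shared_partial": shared_partial,
        "major_shared": [nd.sequence for nd in major[:top_k]],
    }
    if sum(exclusive.values()) + shared_all + shared_partial != total:
        # partition identity is structural; failing it indicates a bug
        warnings.warn("haplotype sharing categories do not partition the node set")
    return summary
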