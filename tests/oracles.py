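"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools
import math


def mst_weight_bruteforce(dist) -> int:
    """Minimum spanning tree weight by exhaustive enumeration.

    Enumerates every labeled tree on n nodes via its Pruefer sequence
    (Cayley: n^(n-2) trees) and takes the minimum total weight. Only
    feasible for n <= 7; completely independent of any greedy MST
    algorithm.
    """
    n = len(dist)
    if n == 1:
        return 0
    if n == 2:
        return int(dist[0][1])
    best = math.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        weight = 0
        deg = list(degree)
        ptr_seq = list(seq)
        leaves = sorted(i for i in range(n) if deg[i] == 1)
        import heapq

        heapq.heapify(leaves)
        for x in ptr_seq:
            leaf = heapq.heappop(leaves)
            weight += dist[leaf][x]
            deg[x] -= 1
            if deg[x] == 1:
                heapq.heappush(leaves, x)
        u = heapq.heappop(leaves)
        v = heapq.heappop(leaves)
        weight += dist[u][v]
        if weight < best:
            best = weight
    return int(best)


def rotation_strand_identity(a: str, b: str) -> float:
    """Best ungapped percent identity of a vs all rotations/strands of b.

    Valid only for equal-length sequences; serves as the phase-matching
    oracle for the alignment-based identity measure.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(b))
    best = 0.0
    for variant in (b, rc):
        for r in range(len(variant)):
            rot = variant[r:] + variant[:r]
            matches = sum(x == y and x != "N" for x, y in zip(a, rot))
            best = max(best, 100.0 * matches / len(a))
    return best
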