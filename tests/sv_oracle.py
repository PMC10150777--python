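"""Independent exhaustive oracle for SV consensus matching.

Enumerates every matching of caller-a calls to caller-b calls (per
connected component of the feasibility graph) and returns the maximum
cardinality and, among maximum matchings, the minimum total breakpoint
delta.  Shares nothing with the implementation under test except the
published tolerance rule, restated here from scratch.
"""

import numpy as np


def tolerance(length):
    if length <= 10_000:
        return 100
    if length <= 50_000:
        return 1_000
    return 10_000


def feasible_pairs(calls_a, calls_b):
    pairs = []
    for i, xa in enumerate(calls_a):
        for j, xb in enumerate(calls_b):
            if xa["chrom"] != xb["chrom"] or xa["svtype"] != xb["svtype"]:
                continue
            mean_len = ((xa["end"] - xa["start"] + 1) + (xb["end"] - xb["start"] + 1)) / 2
            tol = tolerance(mean_len)
            ds = abs(xa["start"] - xb["start"])
            de = abs(xa["end"] - xb["end"])
            if ds <= tol and de <= tol:
                pairs.append((i, j, ds + de))
    return pairs


def best_matching(calls_a, calls_b):
    """(max cardinality, min total delta among maximum matchings)."""
    pairs = feasible_pairs(calls_a, calls_b)
    # connected components over the bipartite feasibility graph
    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in pairs:
        ra, rb = find(("a", i)), find(("b", j))
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for i, j, d in pairs:
        comps.setdefault(find(("a", i)), []).append((i, j, d))

    total_n, total_d = 0, 0
    for comp_pairs in comps.values():
        best = (0, 0)

        def rec(idx, used_a, used_b, n, d):
            nonlocal best
            if (n, -d) > (best[0], -best[1]):
                best = (n, d)
            for k in range(idx, len(comp_pairs)):
                i, j, dk = comp_pairs[k]
                if i in used_a or j in used_b:
                    continue
                rec(k + 1, used_a | {i}, used_b | {j}, n + 1, d + dk)

        rec(0, frozenset(), frozenset(), 0, 0)
        total_n += best[0]
        total_d += best[1]
    return total_n, total_d


def random_instance(rng, max_calls=20, max_per_cluster=3):
    """Random dual-caller callsets with clustered events forcing ambiguity.

    Calls per caller are spread over clusters with at most
    ``max_per_cluster`` calls per caller per cluster, which keeps the
    feasibility components small enough for exhaustive enumeration while
    still exercising ambiguous many-to-many configurations.
    """
    na, nb = rng.integers(1, max_calls + 1, size=2)
    n_clusters = int(max(1, -(-max(na, nb) // max_per_cluster)) + rng.integers(0, 3))
    centers = rng.integers(10_000, 10_000_000, size=n_clusters)
    lengths = (10 ** rng.uniform(2.5, 5.5, size=n_clusters)).astype(int)
    svtypes = rng.choice(["DEL", "DUP", "INV"], size=n_clusters)

    def make(n):
        slots = np.repeat(np.arange(n_clusters), max_per_cluster)
        chosen = rng.permutation(slots)[:n]
        calls = []
        for c in chosen:
            start = int(centers[c] + rng.integers(-300, 301))
            end = start + int(lengths[c] + rng.integers(-300, 301))
            calls.append(
                {"chrom": "chr1", "start": start, "end": max(end, start),
                 "svtype": str(svtypes[c]), "sample_id": "S1"}
            )
        return calls

    return make(int(na)), make(int(nb))
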