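"""Independent brute-force oracles used only by the test suite."""

import itertools


def dp_levenshtein(a: str, b: str) -> int:
    """Full dynamic-programming matrix edit distance (no shortcuts)."""
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
    return d[n][m]


def brute_force_edges(tcrs, d_max, same_vj=False):
    """All-pairs thresholded edge set over receptors."""
    tcrs = sorted(set(tcrs), key=lambda t: t.key)
    edges = set()
    for a, b in itertools.combinations(tcrs, 2):
        if same_vj and (a.v_gene != b.v_gene or a.j_gene != b.j_gene):
            continue
        if dp_levenshtein(a.cdr3_aa, b.cdr3_aa) <= d_max:
            edges.add(frozenset((a, b)))
    return edges


def brute_force_max_clique_size(adj_sets, n):
    """Maximum clique size by exhaustive bitmask enumeration (2^n subsets)."""
    masks = [0] * n
    for i in range(n):
        for j in adj_sets[i]:
            masks[i] |= 1 << j
    best = 0
    for subset in range(1, 1 << n):
        size = subset.bit_count()
        if size <= best:
            continue
        ok = True
        s = subset
        while s:
            i = (s & -s).bit_length() - 1
            s &= s - 1
            if (subset & ~(masks[i] | (1 << i))) != 0:
                ok = False
                break
        if ok:
            best = size
    return best
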