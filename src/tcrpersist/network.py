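"""CDR3 amino-acid similarity networks.

Receptors are nodes; an edge joins two receptors whose CDR3 amino-acid
sequences are within a Levenshtein edit distance cutoff (default 1), a
standard proxy for putative shared antigen specificity.  Nodes are binned by
neighbor count into deciles of the maximum observed degree, and a permutation
test asks whether well-connected receptors are observed at more time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import edlib
import networkx as nx
import numpy as np
from scipy import stats as sps

from .persistence import OccurrenceProfile
from .types import TcrBeta


def levenshtein(a: str, b: str, k: int | None = None) -> int:
    """Unit-cost Levenshtein distance between two sequences.

    With ``k`` given, distances greater than ``k`` are reported as -1
    (early-terminated banded computation).
    """
    if a == b:
        return 0
    res = edlib.align(a, b, mode="NW", task="distance", k=-1 if k is None else k)
    return int(res["editDistance"])


def _deletion_variants(s: str) -> Iterable[str]:
    for i in range(len(s)):
        yield s[:i] + s[i + 1 :]


def _candidate_pairs_d1(cdr3s: Sequence[str]) -> set[tuple[int, int]]:
    """Candidate index pairs possibly within edit distance 1.

    Symmetric-deletion indexing: two strings are within one edit iff they are
    equal, one is a single-deletion variant of the other, or deleting one
    (aligned) position from each yields the same string.  Every such pair
    shares an entry in the index of {string} | {its single-deletion variants};
    candidates are verified exactly afterwards.
    """
    index: dict[str, list[int]] = {}
    for i, s in enumerate(cdr3s):
        index.setdefault(s, []).append(i)
        for v in set(_deletion_variants(s)):
            index.setdefault(v, []).append(i)
    pairs: set[tuple[int, int]] = set()
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for ai in range(len(bucket)):
            for bi in range(ai + 1, len(bucket)):
                i, j = bucket[ai], bucket[bi]
                if i != j:
                    pairs.add((min(i, j), max(i, j)))
    return pairs


def build_similarity_graph(
    tcrs: Iterable[TcrBeta], d_max: int = 1, same_vj: bool = False
) -> nx.Graph:
    """Graph with receptor nodes and edges at CDR3 distance <= ``d_max``.

    V/J genes are ignored for edge formation unless ``same_vj`` is set, in
    which case both genes must match.  Receptors with identical CDR3s but
    different V/J are distinct nodes joined at distance 0.  Construction is
    exact (equal to all-pairs thresholding); for ``d_max == 1`` a
    symmetric-deletion index avoids the quadratic scan, otherwise length
    bucketing plus banded early termination is used.
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    nodes = sorted(set(tcrs), key=lambda t: t.key)
    g = nx.Graph()
    g.add_nodes_from(nodes)

    cdr3s = sorted({t.cdr3_aa for t in nodes})
    by_cdr3: dict[str, list[TcrBeta]] = {}
    for t in nodes:
        by_cdr3.setdefault(t.cdr3_aa, []).append(t)

    def compatible(u: TcrBeta, v: TcrBeta) -> bool:
        return not same_vj or (u.v_gene == v.v_gene and u.j_gene == v.j_gene)

    # distance-0 edges: identical CDR3, distinct receptor identity
    for group in by_cdr3.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if compatible(group[i], group[j]):
                    g.add_edge(group[i], group[j], distance=0)

    if d_max >= 1:
        if d_max == 1:
            cand = _candidate_pairs_d1(cdr3s)
        else:
            cand = set()
            by_len: dict[int, list[int]] = {}
            for i, s in enumerate(cdr3s):
                by_len.setdefault(len(s), []).append(i)
            for la, idx_a in by_len.items():
                for lb, idx_b in by_len.items():
                    if lb < la or lb - la > d_max:
                        continue
                    for i in idx_a:
                        for j in idx_b:
                            if i != j:
                                cand.add((min(i, j), max(i, j)))
        for i, j in cand:
            d = levenshtein(cdr3s[i], cdr3s[j], k=d_max)
            if 0 < d <= d_max:
                for u in by_cdr3[cdr3s[i]]:
                    for v in by_cdr3[cdr3s[j]]:
                        if compatible(u, v):
                            g.add_edge(u, v, distance=d)
    return g


@dataclass(slots=True)
class NeighborBinTable:
    """Receptors partitioned into degree-decile bins.

    A node with degree d lands in bin ``min(10 * d // max_degree, 9)``; bin b
    spans degrees in [b*10%, (b+1)*10%) of the maximum observed degree (the
    top bin is closed).  With no edges at all, every node sits in bin 0.
    """

    bins: list[set[TcrBeta]]
    degree: dict[TcrBeta, int]
    max_degree: int

    @property
    def labels(self) -> list[str]:
        return [f"{10 * b}-{10 * (b + 1)}%" for b in range(10)]


def neighbor_decile_bins(g: nx.Graph) -> NeighborBinTable:
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    degree = {n: d for n, d in g.degree()}
    max_degree = max(degree.values())
    bins: list[set[TcrBeta]] = [set() for _ in range(10)]
    for n, d in degree.items():
        b = 0 if max_degree == 0 else min(10 * d // max_degree, 9)
        bins[b].add(n)
    return NeighborBinTable(bins=bins, degree=degree, max_degree=max_degree)


class ConnectivityTrend(NamedTuple):
    histograms: "np.ndarray"  # shaped (10, T): per-bin fraction at each n
    trend: float  # Spearman rho between node degree and n


def persistence_by_connectivity(
    bins: NeighborBinTable, profile: OccurrenceProfile
):
    """Per-bin occurrence histograms plus the degree-vs-occurrence trend.

    The trend statistic is the Spearman correlation between node degree and
    the number of time points observed, computed on nodes (monotone-invariant
    and independent of the binning).  Returns ``(histogram DataFrame, trend)``;
    non-empty histogram rows each sum to 1.
    """
    import pandas as pd

    missing = [n for n in bins.degree if n not in profile.counts]
    if missing:
        keys = ", ".join(str(m) for m in sorted(missing, key=lambda t: t.key)[:5])
        raise ValueError(
            f"{len(missing)} graph nodes missing from occurrence profile: {keys} ..."
        )
    t_max = profile.n_timepoints
    hist = np.zeros((10, t_max))
    for b, members in enumerate(bins.bins):
        for tcr in members:
            hist[b, profile[tcr] - 1] += 1
        total = hist[b].sum()
        if total > 0:
            hist[b] /= total
    nodes = sorted(bins.degree, key=lambda t: t.key)
    deg = np.array([bins.degree[n] for n in nodes], dtype=float)
    occ = np.array([profile[n] for n in nodes], dtype=float)
    trend = _spearman_or_zero(deg, occ)
    df = pd.DataFrame(
        hist,
        index=pd.Index(bins.labels, name="neighbor_bin"),
        columns=pd.Index(range(1, t_max + 1), name="n_timepoints"),
    )
    return df, trend


def _spearman_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho, 0 when either side is constant (no trend definable)."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def connectivity_permutation_test(
    bins: NeighborBinTable,
    profile: OccurrenceProfile,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the degree-vs-persistence trend.

    Occurrence counts are shuffled across nodes while the graph (hence every
    degree) stays fixed; p = (1 + #{permuted trend >= observed}) / (1 + n_perm)
    with the add-one convention, so p is never below 1/(n_perm + 1).
    """
    nodes = sorted(bins.degree, key=lambda t: t.key)
    deg = np.array([bins.degree[n] for n in nodes], dtype=float)
    occ = np.array([profile[n] for n in nodes], dtype=float)
    if n_perm < 1:
        return 1.0
    rng = np.random.default_rng(seed)
    # Spearman = Pearson on ranks; degree ranks are fixed, occurrence ranks permute
    rd = sps.rankdata(deg)
    ro = sps.rankdata(occ)
    rd_c = rd - rd.mean()
    ro_c = ro - ro.mean()
    denom = np.sqrt((rd_c**2).sum() * (ro_c**2).sum())
    if denom == 0:
        # a constant side: the trend is 0 under every relabelling
        return 1.0
    observed = float(rd_c @ ro_c) / denom
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(ro_c)
        if (rd_c @ perm) / denom >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
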