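"""Detection of clonal cohorts: sets of expanded receptors whose abundance
trajectories track one another across time.

Candidates are receptors ranked in the top 1% by abundance in at least two
PBMC samples (expanded clones).  Their trajectories, with absences imputed by
each sample's median receptor abundance, form a correlation graph (edges at
correlation > 0.95), in which the maximum clique is the reported cohort.
Significance comes from re-running the whole construction on datasets where
each receptor's values are independently shuffled across sample labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .io import collapse_to_tcrs
from .network import levenshtein
from .stats import abundance_vector, top_fraction
from .types import TcrBeta, TimeSeriesRepertoire


def select_expanded(
    series: TimeSeriesRepertoire, fraction: float = 0.01, min_times: int = 2
) -> set[TcrBeta]:
    """Receptors in the per-sample top ``fraction`` in >= ``min_times`` PBMC samples."""
    if len(series.pbmc_samples) < min_times:
        raise ValueError("series has fewer samples than min_times")
    hits: dict[TcrBeta, int] = {}
    for sample in series.pbmc_samples:
        for tcr in top_fraction(sample, fraction):
            hits[tcr] = hits.get(tcr, 0) + 1
    return {tcr for tcr, k in hits.items() if k >= min_times}


@dataclass(slots=True)
class TrajectoryMatrix:
    """Candidate-by-timepoint abundance matrix with median imputation.

    ``observed`` marks entries actually measured; the rest were filled with
    the corresponding sample's median productive receptor abundance.
    """

    tcrs: list[TcrBeta]
    time_points: list[int]
    values: np.ndarray  # (n_candidates, T), imputed
    observed: np.ndarray  # (n_candidates, T) bool
    medians: np.ndarray  # (T,) per-sample median abundance

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def trajectory_matrix(
    series: TimeSeriesRepertoire, candidates: Sequence[TcrBeta] | set[TcrBeta]
) -> TrajectoryMatrix:
    """Assemble trajectories for ``candidates`` over the PBMC series.

    The imputation value for a sample is the median abundance over *all* of
    that sample's productive receptors, not just the candidates — absent
    receptors are assumed about as abundant as a typical undetected one.
    """
    tcrs = sorted(set(candidates), key=lambda t: t.key)
    vectors = [abundance_vector(s) for s in series.pbmc_samples]
    observed_any = set().union(*[set(v) for v in vectors]) if vectors else set()
    missing = [t for t in tcrs if t not in observed_any]
    if missing:
        raise ValueError(f"{len(missing)} candidates never observed in the series")
    t_pts = [s.time_point for s in series.pbmc_samples]
    medians = np.array([np.median(list(v.values())) if v else 0.0 for v in vectors])
    n, T = len(tcrs), len(t_pts)
    values = np.tile(medians, (n, 1))
    observed = np.zeros((n, T), dtype=bool)
    for j, v in enumerate(vectors):
        for i, tcr in enumerate(tcrs):
            if tcr in v:
                values[i, j] = v[tcr]
                observed[i, j] = True
    return TrajectoryMatrix(tcrs, t_pts, values, observed, medians)


def _pairwise_correlation(values: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        values = sps.rankdata(values, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.corrcoef(values)


def correlation_graph(
    m: TrajectoryMatrix,
    method: str = "spearman",
    threshold: float = 0.95,
    inclusive: bool = False,
) -> nx.Graph:
    """Graph over candidates with edges at trajectory correlation > threshold.

    The comparison is strict by default (``inclusive`` switches to >=).
    Zero-variance rows cannot be correlated and are dropped with a warning.
    """
    if len(m.time_points) < 3:
        raise ValueError("need at least 3 time points to correlate trajectories")
    var = m.values.var(axis=1)
    keep = var > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance trajectories", stacklevel=2
        )
    g = nx.Graph()
    idx = np.flatnonzero(keep)
    for i in idx:
        g.add_node(m.tcrs[i])
    if len(idx) >= 2:
        corr = _pairwise_correlation(m.values[idx], method)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                c = corr[a, b]
                if np.isfinite(c) and (c >= threshold if inclusive else c > threshold):
                    g.add_edge(m.tcrs[idx[a]], m.tcrs[idx[b]], correlation=float(c))
    return g


def _node_key(node):
    return node.key if isinstance(node, TcrBeta) else node


def max_clique(g: nx.Graph) -> set:
    """A maximum-cardinality clique, with a deterministic tie-break.

    Among all maximum cliques the lexicographically smallest member-key set
    wins.  Empty graph -> empty set; an edgeless graph yields the single
    smallest node.
    """
    if g.number_of_nodes() == 0:
        return set()
    best: tuple[int, tuple] | None = None
    best_set: set = set()
    for clique in nx.find_cliques(g):
        key = tuple(sorted(_node_key(n) for n in clique))
        cand = (-len(clique), key)
        if best is None or cand < best:
            best = cand
            best_set = set(clique)
    return best_set


def _clique_number(adj: np.ndarray) -> int:
    """Size of the maximum clique of a boolean adjacency matrix."""
    g = nx.from_numpy_array(adj)
    if g.number_of_nodes() == 0:
        return 0
    return max((len(c) for c in nx.find_cliques(g)), default=0)


def cohort_significance(
    series: TimeSeriesRepertoire,
    observed_clique_size: int,
    n_perm: int = 1000,
    seed: int | None = None,
    fraction: float = 0.01,
    min_times: int = 2,
    method: str = "spearman",
    threshold: float = 0.95,
    inclusive: bool = False,
) -> float:
    """Permutation p-value for the observed maximum-clique (cohort) size.

    Each shuffled dataset independently permutes every candidate receptor's
    abundance values across sample labels (missing entries travel with the
    shuffle); imputation, the correlation graph and the maximum clique are
    then recomputed in full.  p uses the add-one convention.
    """
    if n_perm < 1:
        return 1.0
    candidates = select_expanded(series, fraction, min_times)
    if len(candidates) < 2:
        return 1.0
    m = trajectory_matrix(series, candidates)
    raw = np.where(m.observed, m.values, np.nan)
    rng = np.random.default_rng(seed)
    n, T = raw.shape
    exceed = 0
    for _ in range(n_perm):
        order = np.argsort(rng.random((n, T)), axis=1)
        shuffled = np.take_along_axis(raw, order, axis=1)
        filled = np.where(np.isnan(shuffled), m.medians[None, :], shuffled)
        keep = filled.var(axis=1) > 0
        kept = filled[keep]
        if kept.shape[0] < 2:
            size = min(1, kept.shape[0])
        else:
            corr = _pairwise_correlation(kept, method)
            np.fill_diagonal(corr, 0.0)
            adj = (corr >= threshold) if inclusive else (corr > threshold)
            adj &= np.isfinite(corr)
            size = _clique_number(adj)
        if size >= observed_clique_size:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


@dataclass(slots=True)
class CohortResult:
    """One detected cohort: the maximum clique of the correlation graph."""

    members: list[TcrBeta]
    method: str
    threshold: float
    clique_size: int
    permutation_p: float | None
    artifact_flags: dict[TcrBeta, bool] = field(default_factory=dict)


def flag_artifact_suspects(
    members: Sequence[TcrBeta],
    mean_abundance: Mapping[TcrBeta, float],
    abundance_ratio: float = 0.1,
    d_max: int = 2,
) -> dict[TcrBeta, bool]:
    """Flag cohort members that look like sequencing-error satellites.

    A member is suspect when its mean abundance is below ``abundance_ratio``
    of the cohort's most abundant member *and* its CDR3 is within
    ``d_max`` edits of that member's CDR3 — the signature of errors shadowing
    a dominant clone.  The dominant member itself is never flagged.
    """
    if not members:
        return {}
    dominant = max(members, key=lambda t: (mean_abundance[t], t.key))
    cutoff = abundance_ratio * mean_abundance[dominant]
    flags: dict[TcrBeta, bool] = {}
    for t in members:
        flags[t] = (
            t != dominant
            and mean_abundance[t] < cutoff
            and levenshtein(t.cdr3_aa, dominant.cdr3_aa, k=d_max) >= 0
        )
    return flags


def find_cohort(
    series: TimeSeriesRepertoire,
    method: str = "spearman",
    threshold: float = 0.95,
    fraction: float = 0.01,
    min_times: int = 2,
    n_perm: int = 1000,
    seed: int | None = None,
    inclusive: bool = False,
) -> CohortResult:
    """End-to-end cohort detection for one individual's series."""
    candidates = select_expanded(series, fraction, min_times)
    if len(candidates) < 2:
        return CohortResult([], method, threshold, 0, None)
    m = trajectory_matrix(series, candidates)
    g = correlation_graph(m, method=method, threshold=threshold, inclusive=inclusive)
    clique = max_clique(g)
    members = sorted(clique, key=lambda t: t.key)
    p = None
    if len(members) >= 2 and n_perm >= 1:
        p = cohort_significance(
            series, len(members), n_perm=n_perm, seed=seed, fraction=fraction,
            min_times=min_times, method=method, threshold=threshold,
            inclusive=inclusive,
        )
    mean_ab = {
        t: float(np.mean(m.values[m.tcrs.index(t)][m.observed[m.tcrs.index(t)]]))
        for t in members
    }
    flags = flag_artifact_suspects(members, mean_ab) if members else {}
    return CohortResult(members, method, threshold, len(members), p, flags)
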