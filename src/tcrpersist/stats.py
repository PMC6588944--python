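"""Per-sample and cross-sample repertoire summary statistics.

Covers receptor-set overlap (Jaccard), alpha diversity (Shannon estimate,
``exp(H)`` with natural-log entropy), clonality (1 - Pielou's evenness),
shared-receptor abundance correlations, V/J gene usage, CDR3 length
distributions, high-abundance subsetting and rarefaction.

An *abundance vector* is a mapping ``TcrBeta -> relative abundance``.  The
values need not sum to 1: nonproductive sequencing mass stays in every
frequency's denominator but is excluded from the productive receptor set.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import collapse_to_tcrs
from .types import RepertoireSample, TcrBeta

AbundanceVector = Mapping[TcrBeta, float]


def abundance_vector(sample: RepertoireSample) -> dict[TcrBeta, float]:
    """Productive receptor -> relative abundance for one sample."""
    return {tcr: agg.abundance for tcr, agg in collapse_to_tcrs(sample).items()}


def jaccard_index(a: Iterable[TcrBeta], b: Iterable[TcrBeta]) -> float:
    """|a & b| / |a | b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def jaccard_matrix(samples: Sequence[RepertoireSample]) -> pd.DataFrame:
    """Pairwise Jaccard indexes over productive receptor sets.

    Returns a symmetric DataFrame with unit diagonal, labelled by each
    sample's ``individual/timepoint/compartment`` tag.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    sets = [set(abundance_vector(s)) for s in samples]
    labels = [s.label for s in samples]
    n = len(samples)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jaccard_index(sets[i], sets[j])
    return pd.DataFrame(m, index=labels, columns=labels)


def _renormalized(v: AbundanceVector) -> np.ndarray:
    if len(v) == 0:
        raise ValueError("empty abundance vector")
    p = np.asarray(list(v.values()), dtype=float)
    if np.any(p <= 0) or not np.all(np.isfinite(p)):
        raise ValueError("abundances must be positive and finite")
    return p / p.sum()


def shannon_diversity(v: AbundanceVector) -> float:
    """Shannon diversity estimate ``exp(H)``, H in nats on renormalized abundances.

    Equals the number of receptors for a perfectly even repertoire and 1 for
    a monoclonal one ("effective number of receptors").
    """
    p = _renormalized(v)
    return float(np.exp(sps.entropy(p)))


def clonality(v: AbundanceVector) -> float:
    """Clonality = 1 - Pielou's evenness = 1 - H / ln(S).

    0 for a perfectly even repertoire, approaching 1 under extreme clonal
    dominance.  Defined as 0 for a single-receptor vector (evenness limit 1).
    """
    p = _renormalized(v)
    s = len(p)
    if s == 1:
        return 0.0
    return float(1.0 - sps.entropy(p) / math.log(s))


def top_fraction(
    sample: RepertoireSample | AbundanceVector, fraction: float = 0.01
) -> set[TcrBeta]:
    """The ceil(fraction * S) highest-abundance receptors of a sample.

    Ties at the cutoff break by lexicographic receptor key, so the result is
    deterministic.  An empty sample yields an empty set.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    v = abundance_vector(sample) if isinstance(sample, RepertoireSample) else sample
    if not v:
        return set()
    k = math.ceil(fraction * len(v))
    ranked = sorted(v.items(), key=lambda kv: (-kv[1], kv[0].key))
    return {tcr for tcr, _ in ranked[:k]}


class SharedCorrelation(NamedTuple):
    n_shared: int
    coefficient: float
    p: float


class UndefinedCorrelationError(ValueError):
    """Too few shared receptors for a correlation to be meaningful."""


def shared_abundance_correlation(
    a: AbundanceVector, b: AbundanceVector, method: str = "spearman"
) -> SharedCorrelation:
    """Correlation of abundances over receptors shared between two samples.

    Only the intersection of the two key sets enters the calculation; the
    number of shared receptors is reported alongside the coefficient and the
    standard large-sample p-value.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    shared = sorted(set(a) & set(b), key=lambda t: t.key)
    if len(shared) < 3:
        raise UndefinedCorrelationError(
            f"only {len(shared)} shared receptors; need >= 3"
        )
    x = np.array([a[t] for t in shared])
    y = np.array([b[t] for t in shared])
    if method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        res = sps.pearsonr(x, y)
    return SharedCorrelation(len(shared), float(res.statistic), float(res.pvalue))


def vj_usage(sample: RepertoireSample) -> pd.DataFrame:
    """V and J gene usage as unique-receptor and total-abundance fractions.

    Within each segment class (V, J) both fraction columns sum to 1.
    """
    v = abundance_vector(sample)
    rows = []
    for segment, getter in (("V", lambda t: t.v_gene), ("J", lambda t: t.j_gene)):
        unique: dict[str, int] = {}
        mass: dict[str, float] = {}
        for tcr, ab in v.items():
            g = getter(tcr)
            unique[g] = unique.get(g, 0) + 1
            mass[g] = mass.get(g, 0.0) + ab
        n_unique = sum(unique.values())
        total_mass = sum(mass.values())
        for g in sorted(unique):
            rows.append(
                {
                    "segment": segment,
                    "gene": g,
                    "unique_fraction": unique[g] / n_unique,
                    "abundance_fraction": mass[g] / total_mass,
                }
            )
    return pd.DataFrame(rows, columns=["segment", "gene", "unique_fraction", "abundance_fraction"])


def cdr3_length_distribution(
    tcrs: Iterable[TcrBeta], weights: AbundanceVector | None = None
) -> dict[int, float]:
    """Histogram of CDR3 amino-acid lengths, by count or by abundance mass."""
    hist: dict[int, float] = {}
    for tcr in tcrs:
        w = 1.0 if weights is None else weights.get(tcr, 0.0)
        hist[len(tcr.cdr3_aa)] = hist.get(len(tcr.cdr3_aa), 0.0) + w
    return dict(sorted(hist.items()))


def rarefaction_curve(
    sample: RepertoireSample,
    depths: Sequence[int],
    n_reps: int = 10,
    seed: int | None = None,
) -> dict[int, float]:
    """Mean unique productive receptor count in without-replacement subsamples.

    Templates (productive and nonproductive) are subsampled without
    replacement via a multivariate hypergeometric draw; at full depth the
    curve equals the observed richness exactly.
    """
    total = sample.total_count
    depths = [int(d) for d in depths]
    for d in depths:
        if d > total:
            raise ValueError(f"depth {d} exceeds total template count {total}")
        if d < 1:
            raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.array([r.count for r in sample.records], dtype=np.int64)
    tcr_ids = np.array(
        [
            -1 if not r.productive else i
            for i, r in enumerate(sample.records)
        ]
    )
    # map records to receptor index (several nt clones may share a receptor)
    keys: dict[tuple, int] = {}
    for i, r in enumerate(sample.records):
        if r.productive:
            k = (r.cdr3_aa, r.v_gene, r.j_gene)
            tcr_ids[i] = keys.setdefault(k, len(keys))
    out: dict[int, float] = {}
    for d in depths:
        if d == total:
            out[d] = float(len(keys))
            continue
        vals = []
        for _ in range(n_reps):
            sub = rng.multivariate_hypergeometric(counts, d)
            present = np.unique(tcr_ids[(sub > 0) & (tcr_ids >= 0)])
            vals.append(len(present))
        out[d] = float(np.mean(vals))
    return out
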