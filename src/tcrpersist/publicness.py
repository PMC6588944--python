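"""Publicness: sharing of receptors across an external reference cohort,
and its relationship with within-individual persistence.

A receptor's *share fraction* is the number of cohort subjects carrying it
divided by the cohort size; "highly public" means shared by more than 70% of
subjects (strict inequality).  Enrichment of persistent receptors among
highly public ones is tested both with an independent two-sample t-test
across individuals and a per-individual permutation test.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .persistence import OccurrenceProfile, persistent_set
from .types import TcrBeta


@dataclass(slots=True)
class SharingTable:
    """Map receptor -> number of subjects (out of ``cohort_size``) sharing it.

    Receptors absent from the table look up as 0: the cohort table enumerates
    observed receptors, and absence is informative privacy.
    """

    cohort_size: int
    counts: dict[TcrBeta, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        for tcr, c in self.counts.items():
            if not 0 <= c <= self.cohort_size:
                raise ValueError(f"share count {c} outside [0, {self.cohort_size}] for {tcr}")

    def share_count(self, tcr: TcrBeta) -> int:
        return self.counts.get(tcr, 0)

    def share_fraction(self, tcr: TcrBeta) -> float:
        return self.counts.get(tcr, 0) / self.cohort_size

    def __len__(self) -> int:
        return len(self.counts)

    def to_tsv(self, path) -> None:
        lines = [f"# cohort_size={self.cohort_size}",
                 "aminoAcid\tvGeneName\tjGeneName\tn_shared"]
        for tcr in sorted(self.counts, key=lambda t: t.key):
            lines.append(
                f"{tcr.cdr3_aa}\t{tcr.v_gene}\t{tcr.j_gene}\t{self.counts[tcr]}"
            )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path, cohort_size: int | None = None) -> "SharingTable":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        header_size = None
        body_lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                if "cohort_size=" in line:
                    header_size = int(line.split("cohort_size=")[1].strip())
            else:
                body_lines.append(line)
        size = cohort_size if cohort_size is not None else header_size
        if size is None:
            raise ValueError("cohort size neither in file header nor given explicitly")
        df = pd.read_csv(_io.StringIO("\n".join(body_lines)), sep="\t", dtype=str)
        count_col = "n_shared" if "n_shared" in df.columns else "n_cmv_public"
        counts = {
            TcrBeta(r["vGeneName"], r["aminoAcid"], r["jGeneName"]): int(r[count_col])
            for _, r in df.iterrows()
        }
        return cls(cohort_size=size, counts=counts)


@dataclass(slots=True)
class PublicnessBins:
    """Receptors partitioned into ten share-fraction decile bins.

    A receptor with share fraction f lands in bin ``min(floor(10 f), 9)``;
    f = 1 is clamped into the top "90-100%" bin.
    """

    bins: list[set[TcrBeta]]
    share_fraction: dict[TcrBeta, float]

    @property
    def labels(self) -> list[str]:
        return [f"{10 * b}-{10 * (b + 1)}%" for b in range(10)]


def publicness_bins(tcrs: Iterable[TcrBeta], sharing: SharingTable) -> PublicnessBins:
    bins: list[set[TcrBeta]] = [set() for _ in range(10)]
    fracs: dict[TcrBeta, float] = {}
    for tcr in tcrs:
        f = sharing.share_fraction(tcr)
        fracs[tcr] = f
        bins[min(int(10 * f), 9)].add(tcr)
    return PublicnessBins(bins=bins, share_fraction=fracs)


def occurrence_by_publicness(
    bins: PublicnessBins, profile: OccurrenceProfile
) -> tuple[pd.DataFrame, pd.Series]:
    """Occurrence histograms per publicness bin, and mean share per class.

    Returns ``(histograms, mean_share)``: histograms is bins x n with
    non-empty rows summing to 1; mean_share gives, per occurrence class n,
    the mean share fraction of its members (the transposed view).
    """
    t_max = profile.n_timepoints
    hist = np.zeros((10, t_max))
    share_sum = np.zeros(t_max)
    share_n = np.zeros(t_max)
    for b, members in enumerate(bins.bins):
        for tcr in members:
            n = profile[tcr]
            hist[b, n - 1] += 1
            share_sum[n - 1] += bins.share_fraction[tcr]
            share_n[n - 1] += 1
        if hist[b].sum() > 0:
            hist[b] /= hist[b].sum()
    df = pd.DataFrame(
        hist,
        index=pd.Index(bins.labels, name="publicness_bin"),
        columns=pd.Index(range(1, t_max + 1), name="n_timepoints"),
    )
    with np.errstate(invalid="ignore"):
        mean_share = share_sum / share_n
    series = pd.Series(mean_share, index=df.columns, name="mean_share_fraction")
    return df, series


@dataclass(slots=True)
class EnrichmentResult:
    """Highly-public enrichment of persistent vs single-occurrence receptors."""

    high_threshold: float
    persistent_counts: dict[str, int]
    singleton_counts: dict[str, int]
    t_statistic: float | None
    t_p: float | None
    permutation_p: dict[str, float]

    @property
    def defined(self) -> bool:
        return self.t_statistic is not None or bool(self.permutation_p)


def _highly_public(tcrs: Iterable[TcrBeta], sharing: SharingTable, threshold: float):
    return {t for t in tcrs if sharing.share_fraction(t) > threshold}


def highly_public_enrichment(
    profiles: Mapping[str, OccurrenceProfile],
    sharing: SharingTable,
    high_threshold: float = 0.70,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Do persistent receptors contain more highly public receptors than
    single-occurrence ones?

    Per individual, counts highly public receptors (share fraction strictly
    above ``high_threshold``) among (a) the persistent set and (b) receptors
    seen exactly once; an independent two-sample t-test compares the two
    count groups across individuals.  A per-individual permutation test
    shuffles occurrence counts across receptors and recomputes the
    highly-public count inside the persistent set (add-one p-value).

    With no highly public receptor anywhere, enrichment is undefined and all
    test fields come back absent (None / empty).
    """
    persistent_counts: dict[str, int] = {}
    singleton_counts: dict[str, int] = {}
    high_sets: dict[str, set[TcrBeta]] = {}
    any_high = False
    for ind, profile in profiles.items():
        high = _highly_public(profile.counts, sharing, high_threshold)
        high_sets[ind] = high
        any_high = any_high or bool(high)
        pers = persistent_set(profile)
        once = {t for t, n in profile.items() if n == 1}
        persistent_counts[ind] = len(pers & high)
        singleton_counts[ind] = len(once & high)

    if not any_high:
        return EnrichmentResult(high_threshold, persistent_counts, singleton_counts,
                                None, None, {})

    t_stat = t_p = None
    if len(profiles) >= 2:
        a = np.array(list(persistent_counts.values()), dtype=float)
        b = np.array(list(singleton_counts.values()), dtype=float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            t_stat, t_p = 0.0, 1.0  # identical constant groups
        else:
            with warnings.catch_warnings():
                # near-identical count groups are a legitimate input regime
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.ttest_ind(a, b)
            t_stat, t_p = float(res.statistic), float(res.pvalue)

    rng = np.random.default_rng(seed)
    perm_p: dict[str, float] = {}
    for ind, profile in profiles.items():
        tcrs = sorted(profile.counts, key=lambda t: t.key)
        occ = np.array([profile[t] for t in tcrs])
        is_high = np.array([t in high_sets[ind] for t in tcrs])
        t_max = profile.n_timepoints
        observed = int(np.sum(is_high & (occ == t_max)))
        if n_perm < 1:
            perm_p[ind] = 1.0
            continue
        n_pers = int(np.sum(occ == t_max))
        exceed = 0
        for _ in range(n_perm):
            # shuffling occurrence counts = drawing which receptors are persistent
            pick = rng.choice(len(tcrs), size=n_pers, replace=False)
            if int(is_high[pick].sum()) >= observed:
                exceed += 1
        perm_p[ind] = (1 + exceed) / (1 + n_perm)

    return EnrichmentResult(high_threshold, persistent_counts, singleton_counts,
                            t_stat, t_p, perm_p)


def most_public_report(
    sharing: SharingTable,
    profiles: Mapping[str, OccurrenceProfile],
    top_fraction_threshold: float = 0.90,
) -> pd.DataFrame:
    """Receptors shared by more than ``top_fraction_threshold`` of the cohort,
    with per-individual persistence flags.

    Sorted by descending share count, ties broken lexicographically.
    """
    if not profiles:
        raise ValueError("need at least one occurrence profile")
    pers = {ind: persistent_set(p) for ind, p in profiles.items()}
    rows = []
    for tcr, count in sharing.counts.items():
        f = count / sharing.cohort_size
        if f > top_fraction_threshold:
            row = {
                "cdr3_aa": tcr.cdr3_aa,
                "v_gene": tcr.v_gene,
                "j_gene": tcr.j_gene,
                "share_count": count,
                "share_fraction": f,
            }
            for ind in profiles:
                row[f"persistent_{ind}"] = tcr in pers[ind]
            rows.append((tcr.key, row))
    rows.sort(key=lambda kr: (-kr[1]["share_count"], kr[0]))
    cols = ["cdr3_aa", "v_gene", "j_gene", "share_count", "share_fraction"] + [
        f"persistent_{ind}" for ind in profiles
    ]
    return pd.DataFrame([r for _, r in rows], columns=cols)
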