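"""Persistent-receptor identification and occurrence-class profiling.

A receptor observed in every PBMC time point of an individual's series is
*persistent*.  Receptors are grouped into occurrence classes by the number of
PBMC time points ``n`` at which they were detected, and classes are compared
on mean abundance, nucleotide redundancy, memory/naive compartment overlap
and the share of each sample's productive abundance they carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy import stats as sps

from .io import collapse_to_tcrs
from .types import RepertoireSample, TcrBeta, TimeSeriesRepertoire


@dataclass(slots=True)
class OccurrenceProfile:
    """Per-receptor count of PBMC time points where it was observed."""

    counts: dict[TcrBeta, int]
    n_timepoints: int

    def __getitem__(self, tcr: TcrBeta) -> int:
        return self.counts[tcr]

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self):
        return iter(self.counts)

    def items(self):
        return self.counts.items()


def occurrence_profile(series: TimeSeriesRepertoire) -> OccurrenceProfile:
    """Count, per productive receptor, the PBMC time points where it appears.

    Sorted memory/naive libraries never contribute to the count.
    """
    if not series.pbmc_samples:
        raise ValueError("series has no PBMC samples")
    counts: dict[TcrBeta, int] = {}
    for sample in series.pbmc_samples:
        for tcr in collapse_to_tcrs(sample):
            counts[tcr] = counts.get(tcr, 0) + 1
    return OccurrenceProfile(counts, len(series.pbmc_samples))


def persistent_set(profile: OccurrenceProfile, n_timepoints: int | None = None) -> set[TcrBeta]:
    """Receptors observed at every one of the ``n_timepoints`` PBMC samples."""
    t = profile.n_timepoints if n_timepoints is None else n_timepoints
    if t <= 0:
        raise ValueError("number of time points must be positive")
    return {tcr for tcr, n in profile.items() if n == t}


def _series_aggregates(series: TimeSeriesRepertoire):
    """Per-receptor mean-when-present abundance and union nt redundancy."""
    abund_sum: dict[TcrBeta, float] = {}
    present_n: dict[TcrBeta, int] = {}
    nt_sets: dict[TcrBeta, set[str]] = {}
    for sample in series.pbmc_samples:
        for r in sample.records:
            if not r.productive:
                continue
            tcr = r.tcr
            nt_sets.setdefault(tcr, set()).add(r.cdr3_nt)
        for tcr, agg in collapse_to_tcrs(sample).items():
            abund_sum[tcr] = abund_sum.get(tcr, 0.0) + agg.abundance
            present_n[tcr] = present_n.get(tcr, 0) + 1
    mean_abund = {t: abund_sum[t] / present_n[t] for t in abund_sum}
    nt_red = {t: len(s) for t, s in nt_sets.items()}
    return mean_abund, nt_red


def _union_tcr_set(samples: list[RepertoireSample]) -> set[TcrBeta]:
    out: set[TcrBeta] = set()
    for s in samples:
        out |= set(collapse_to_tcrs(s))
    return out


@dataclass(slots=True)
class OccurrenceClassSummary:
    """Per-occurrence-class metrics plus cumulative abundance by sample.

    ``table`` has one row per class ``n`` in [1, T]; overlap columns are NaN
    when the series lacks sorted compartment samples (absent, not zero).
    ``cumulative_abundance`` is classes x PBMC time points: the fraction of
    each sample's productive abundance contributed by class members.
    """

    table: pd.DataFrame
    cumulative_abundance: pd.DataFrame


def occurrence_class_summary(
    series: TimeSeriesRepertoire, profile: OccurrenceProfile
) -> OccurrenceClassSummary:
    t_max = profile.n_timepoints
    mean_abund, nt_red = _series_aggregates(series)
    classes: dict[int, list[TcrBeta]] = {n: [] for n in range(1, t_max + 1)}
    for tcr, n in profile.items():
        classes[n].append(tcr)

    memory_union = _union_tcr_set(series.memory_samples) if series.memory_samples else None
    naive_union = _union_tcr_set(series.naive_samples) if series.naive_samples else None

    rows = []
    for n in range(1, t_max + 1):
        members = classes[n]
        row: dict = {"n_timepoints": n, "unique_tcr_count": len(members)}
        if members:
            row["mean_abundance"] = sum(mean_abund[t] for t in members) / len(members)
            row["mean_nt_redundancy"] = sum(nt_red[t] for t in members) / len(members)
        else:
            row["mean_abundance"] = float("nan")
            row["mean_nt_redundancy"] = float("nan")
        for name, universe in (("memory_overlap_fraction", memory_union),
                               ("naive_overlap_fraction", naive_union)):
            if universe is None or not members:
                row[name] = float("nan")
            else:
                row[name] = sum(1 for t in members if t in universe) / len(members)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("n_timepoints")

    member_class = dict(profile.items())
    cum = pd.DataFrame(
        0.0,
        index=range(1, t_max + 1),
        columns=[s.time_point for s in series.pbmc_samples],
    )
    cum.index.name = "n_timepoints"
    for sample in series.pbmc_samples:
        for tcr, agg in collapse_to_tcrs(sample).items():
            cum.loc[member_class[tcr], sample.time_point] += agg.abundance
    return OccurrenceClassSummary(table=table, cumulative_abundance=cum)


def compare_occurrence_classes(
    series: TimeSeriesRepertoire,
    metric: str = "abundance",
    profile: OccurrenceProfile | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between occurrence classes.

    ``metric`` is ``"abundance"`` (mean abundance over samples where the
    receptor is present) or ``"nt_redundancy"``.  The reported U statistic is
    that of the lower-n class; small no-tie samples get the exact null,
    larger ones the normal approximation with continuity correction.
    Class pairs with an empty side are flagged ``skipped``.
    """
    if metric not in ("abundance", "nt_redundancy"):
        raise ValueError(f"unknown metric {metric!r}")
    if profile is None:
        profile = occurrence_profile(series)
    mean_abund, nt_red = _series_aggregates(series)
    values = mean_abund if metric == "abundance" else nt_red
    t_max = profile.n_timepoints
    classes: dict[int, list[float]] = {n: [] for n in range(1, t_max + 1)}
    for tcr, n in profile.items():
        classes[n].append(float(values[tcr]))

    rows = []
    for lo in range(1, t_max + 1):
        for hi in range(lo + 1, t_max + 1):
            x, y = classes[lo], classes[hi]
            if not x or not y:
                rows.append(
                    {"n_low": lo, "n_high": hi, "U": float("nan"),
                     "p": float("nan"), "skipped": True}
                )
                continue
            res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True)
            rows.append(
                {"n_low": lo, "n_high": hi, "U": float(res.statistic),
                 "p": float(res.pvalue), "skipped": False}
            )
    return pd.DataFrame(rows, columns=["n_low", "n_high", "U", "p", "skipped"])
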