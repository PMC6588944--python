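"""End-to-end orchestration: from clonotype TSVs or a synthetic cohort to a
directory of report tables.

Stages mirror the analysis narrative: per-sample summary statistics and
overlap/correlation structure, persistence profiling with occurrence-class
comparisons, the CDR3 similarity network with its connectivity permutation
test, correlated clonal-cohort detection, and publicness enrichment.  Every
stochastic stage consumes a seed derived deterministically from the global
seed and the stage name, so identical configurations reproduce numeric
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
import time
import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import cohorts as cohorts_mod
from . import network as network_mod
from . import persistence as pers_mod
from . import publicness as pub_mod
from . import stats as stats_mod
from .config import RunConfig
from .io import collapse_to_tcrs, read_repertoire_tsv, write_repertoire_tsv
from .publicness import SharingTable
from .synthetic import (
    _derived_seed,
    draw_cohort,
    generate_truth,
    truth_sharing_table,
    write_truth_labels,
)
from .types import (
    CloneRecord,
    Compartment,
    RepertoireSample,
    TimeSeriesRepertoire,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


def _write(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def _stage_seed(seed: int, stage: str, *salts: int) -> int:
    return _derived_seed(seed, sum(ord(c) for c in stage), *salts)


def load_inputs(config: RunConfig):
    """Materialize per-individual time series and the sharing table."""
    if config.simulate is not None:
        pool = generate_truth(config.simulate)
        series = draw_cohort(pool, seed=_stage_seed(config.seed, "draw"))
        sharing = truth_sharing_table(pool)
        return series, sharing, pool
    groups: dict[str, dict[str, list[RepertoireSample]]] = {}
    for entry in config.manifest:
        sample = read_repertoire_tsv(
            entry.path, entry.individual, entry.time_point, entry.compartment
        )
        slot = groups.setdefault(entry.individual, {"PBMC": [], "memory": [], "naive": []})
        slot[entry.compartment.value].append(sample)
    series = {
        ind: TimeSeriesRepertoire(ind, g["PBMC"], g["memory"], g["naive"])
        for ind, g in sorted(groups.items())
    }
    sharing = None
    if config.sharing_table:
        sharing = SharingTable.from_tsv(config.sharing_table)
    return series, sharing, None


def summary_stats_table(series: Mapping[str, TimeSeriesRepertoire]) -> pd.DataFrame:
    """Per-sample summary: depth, richness, productive fraction, V/J counts,
    Shannon diversity estimate and clonality."""
    rows = []
    for ind in sorted(series):
        for sample in series[ind].all_samples:
            v = stats_mod.abundance_vector(sample)
            rows.append(
                {
                    "sample": sample.label,
                    "individual": ind,
                    "time_point": sample.time_point,
                    "compartment": sample.compartment.value,
                    "total_templates": sample.total_count,
                    "unique_tcrs": len(v),
                    "productive_fraction": sample.productive_fraction,
                    "unique_v_genes": len({t.v_gene for t in v}),
                    "unique_j_genes": len({t.j_gene for t in v}),
                    "shannon_diversity": stats_mod.shannon_diversity(v) if v else float("nan"),
                    "clonality": stats_mod.clonality(v) if v else float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def correlation_panel(series: Mapping[str, TimeSeriesRepertoire]) -> pd.DataFrame:
    """Shared-receptor Spearman correlations for adjacent same-individual
    month pairs and first-sample cross-individual pairs."""
    rows = []
    vectors = {
        ind: [stats_mod.abundance_vector(s) for s in series[ind].pbmc_samples]
        for ind in series
    }
    for ind in sorted(series):
        pbmc = series[ind].pbmc_samples
        for i in range(len(pbmc) - 1):
            try:
                res = stats_mod.shared_abundance_correlation(
                    vectors[ind][i], vectors[ind][i + 1]
                )
            except stats_mod.UndefinedCorrelationError:
                continue
            rows.append(
                {"kind": "within", "a": pbmc[i].label, "b": pbmc[i + 1].label,
                 "n_shared": res.n_shared, "spearman_rho": res.coefficient, "p": res.p}
            )
    inds = sorted(series)
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            try:
                res = stats_mod.shared_abundance_correlation(
                    vectors[inds[i]][0], vectors[inds[j]][0]
                )
            except stats_mod.UndefinedCorrelationError:
                continue
            rows.append(
                {"kind": "between",
                 "a": series[inds[i]].pbmc_samples[0].label,
                 "b": series[inds[j]].pbmc_samples[0].label,
                 "n_shared": res.n_shared, "spearman_rho": res.coefficient, "p": res.p}
            )
    return pd.DataFrame(rows, columns=["kind", "a", "b", "n_shared", "spearman_rho", "p"])


def restrict_to_top_fraction(
    series: TimeSeriesRepertoire, fraction: float = 0.01
) -> TimeSeriesRepertoire:
    """Keep, in each sample, only records of that sample's top-abundance
    receptors (the undersampling-robustness re-analysis)."""

    def _filter(sample: RepertoireSample) -> RepertoireSample:
        top = stats_mod.top_fraction(sample, fraction)
        records = [
            r for r in sample.records if r.productive and r.tcr in top
        ]
        return RepertoireSample(sample.individual_id, sample.time_point,
                                sample.compartment, records)

    return TimeSeriesRepertoire(
        series.individual_id,
        [_filter(s) for s in series.pbmc_samples],
        [_filter(s) for s in series.memory_samples],
        [_filter(s) for s in series.naive_samples],
    )


def _persistence_outputs(outdir, tag, series, profile):
    summary = pers_mod.occurrence_class_summary(series, profile)
    _write(summary.table, os.path.join(outdir, f"{tag}occurrence_classes.tsv"))
    _write(summary.cumulative_abundance,
           os.path.join(outdir, f"{tag}cumulative_abundance.tsv"))
    for metric in ("abundance", "nt_redundancy"):
        mwu = pers_mod.compare_occurrence_classes(series, metric, profile)
        _write(mwu, os.path.join(outdir, f"{tag}mwu_{metric}.tsv"), index=False)
    annot = pd.DataFrame(
        [
            {"cdr3_aa": t.cdr3_aa, "v_gene": t.v_gene, "j_gene": t.j_gene,
             "n_timepoints_observed": n}
            for t, n in sorted(profile.items(), key=lambda kv: kv[0].key)
        ]
    )
    _write(annot, os.path.join(outdir, f"{tag}tcr_occurrence.tsv"), index=False)
    return summary


def run_pipeline(config: RunConfig) -> str:
    """Execute every stage and write the report directory; returns its path."""
    t0 = time.time()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    stage = "load"
    try:
        series, sharing, pool = load_inputs(config)
        logger.info("loaded %d individuals", len(series))
        if pool is not None:
            write_truth_labels(pool, os.path.join(outdir, "truth_labels.tsv"))
            for ind, ts in series.items():
                for sample in ts.all_samples:
                    write_repertoire_tsv(
                        sample,
                        os.path.join(
                            outdir,
                            f"sample_{ind}_t{sample.time_point}_"
                            f"{sample.compartment.value}.tsv",
                        ),
                    )
        if sharing is not None:
            sharing.to_tsv(os.path.join(outdir, "sharing_table.tsv"))

        stage = "stats"
        _write(summary_stats_table(series), os.path.join(outdir, "summary_stats.tsv"))
        all_samples = [s for ind in sorted(series) for s in series[ind].all_samples]
        if len(all_samples) >= 2:
            _write(stats_mod.jaccard_matrix(all_samples),
                   os.path.join(outdir, "jaccard_matrix.tsv"))
        _write(correlation_panel(series),
               os.path.join(outdir, "correlations.tsv"), index=False)

        profiles: dict[str, pers_mod.OccurrenceProfile] = {}
        for ind in sorted(series):
            ts = series[ind]
            stage = f"persistence[{ind}]"
            profile = pers_mod.occurrence_profile(ts)
            profiles[ind] = profile
            _persistence_outputs(outdir, f"ind{ind}_", ts, profile)
            if config.high_abundance_parallel:
                sub = restrict_to_top_fraction(ts, config.stats.top_fraction)
                sub_profile = pers_mod.occurrence_profile(sub)
                _persistence_outputs(outdir, f"ind{ind}_topfrac_", sub, sub_profile)

            stage = f"network[{ind}]"
            graph = network_mod.build_similarity_graph(
                profile.counts, d_max=config.network.d_max,
                same_vj=config.network.same_vj,
            )
            bins = network_mod.neighbor_decile_bins(graph)
            hist, trend = network_mod.persistence_by_connectivity(bins, profile)
            _write(hist, os.path.join(outdir, f"ind{ind}_network_bins.tsv"))
            p_net = network_mod.connectivity_permutation_test(
                bins, profile, n_perm=config.network.n_perm,
                seed=_stage_seed(config.seed, "network", int(ind)),
            )
            edge_tuples = [
                (u, v, d) if u.key <= v.key else (v, u, d)
                for u, v, d in graph.edges(data="distance")
            ]
            edges = pd.DataFrame(
                [
                    {"tcr_a": str(u), "tcr_b": str(v), "distance": d}
                    for u, v, d in sorted(edge_tuples, key=lambda e: (e[0].key, e[1].key))
                ],
                columns=["tcr_a", "tcr_b", "distance"],
            )
            _write(edges, os.path.join(outdir, f"ind{ind}_network_edges.tsv"),
                   index=False)
            with open(os.path.join(outdir, f"ind{ind}_network_meta.json"), "w") as fh:
                json.dump(
                    {"individual": ind, "d_max": config.network.d_max,
                     "same_vj": config.network.same_vj,
                     "n_nodes": graph.number_of_nodes(),
                     "n_edges": graph.number_of_edges(),
                     "max_degree": bins.max_degree,
                     "trend_spearman": trend,
                     "n_perm": config.network.n_perm,
                     "permutation_p": p_net},
                    fh, indent=1, sort_keys=True,
                )

            stage = f"cohorts[{ind}]"
            cohort_rows = []
            for method in config.cohort.methods:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = cohorts_mod.find_cohort(
                        ts, method=method, threshold=config.cohort.threshold,
                        fraction=config.cohort.fraction,
                        min_times=config.cohort.min_times,
                        n_perm=config.cohort.n_perm,
                        seed=_stage_seed(config.seed, "cohort", int(ind)),
                        inclusive=config.cohort.inclusive,
                    )
                vectors = {
                    s.time_point: stats_mod.abundance_vector(s)
                    for s in ts.pbmc_samples
                }
                for t in result.members:
                    row = {
                        "method": method, "clique_size": result.clique_size,
                        "permutation_p": result.permutation_p,
                        "cdr3_aa": t.cdr3_aa, "v_gene": t.v_gene,
                        "j_gene": t.j_gene,
                        "artifact_flag": result.artifact_flags.get(t, False),
                    }
                    for tp, v in vectors.items():
                        row[f"abundance_t{tp}"] = v.get(t, float("nan"))
                    cohort_rows.append(row)
            _write(pd.DataFrame(cohort_rows),
                   os.path.join(outdir, f"ind{ind}_cohorts.tsv"), index=False)

        if sharing is not None:
            stage = "publicness"
            for ind in sorted(series):
                bins = pub_mod.publicness_bins(profiles[ind].counts, sharing)
                hist, mean_share = pub_mod.occurrence_by_publicness(bins, profiles[ind])
                _write(hist, os.path.join(outdir, f"ind{ind}_publicness_bins.tsv"))
                _write(mean_share.to_frame(),
                       os.path.join(outdir, f"ind{ind}_mean_share_by_occurrence.tsv"))
            enrich = pub_mod.highly_public_enrichment(
                profiles, sharing,
                high_threshold=config.public.high_threshold,
                n_perm=config.public.n_perm,
                seed=_stage_seed(config.seed, "public"),
            )
            with open(os.path.join(outdir, "publicness_enrichment.json"), "w") as fh:
                json.dump(
                    {"high_threshold": enrich.high_threshold,
                     "persistent_highly_public_counts": enrich.persistent_counts,
                     "singleton_highly_public_counts": enrich.singleton_counts,
                     "t_statistic": enrich.t_statistic, "t_p": enrich.t_p,
                     "permutation_p": enrich.permutation_p,
                     "defined": enrich.defined},
                    fh, indent=1, sort_keys=True,
                )
            _write(pub_mod.most_public_report(
                       sharing, profiles, config.public.most_public_threshold),
                   os.path.join(outdir, "most_public_report.tsv"), index=False)

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "individuals": sorted(series),
            "n_samples": {ind: len(series[ind].all_samples) for ind in series},
            "parameters": {
                "stats": vars(config.stats),
                "network": vars(config.network),
                "cohort": {**vars(config.cohort),
                           "methods": list(config.cohort.methods)},
                "public": vars(config.public),
            },
            "high_abundance_parallel": config.high_abundance_parallel,
            "elapsed_seconds": round(time.time() - t0, 1),
        }
        with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    except Exception:
        logger.exception("pipeline failed at stage %s", stage)
        raise
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return outdir
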