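# tcrpersist

Longitudinal TCRβ repertoire analysis: persistent receptors, CDR3
similarity networks, correlated clonal cohorts, and publicness enrichment.

## What this is for

The adaptive immune system maintains millions of unique T cell receptors
(TCRs) per person; the β chain (TCRβ) — a unique combination of V gene,
CDR3 amino-acid sequence and J gene — is the standard tracking unit in
immunosequencing. When the same healthy individual is sampled repeatedly
over a year, most receptors appear only once (deep repertoires are heavily
undersampled by any blood draw), but a small subset is detected at *every*
time point. `tcrpersist` identifies and characterizes that **persistent**
repertoire and its relationship to clonal expansion, sequence similarity,
and **public** receptors shared across unrelated individuals.

The package is for computational immunologists working with immunoSEQ-style
clonotype exports (tab-delimited tables with `aminoAcid`, `vGeneName`,
`jGeneName`, a template-count column), or with the bundled synthetic cohort
generator, which simulates the full study design — individuals × time
points × sorted memory/naive compartments — with known ground truth.

## The statistics at its core

For a sample with productive receptor abundances p₁…p_S (denominators
include nonproductive templates):

* Shannon diversity estimate `e^H`, with `H = −Σ pᵢ ln pᵢ` on renormalized
  abundances, and clonality `1 − H/ln S` (one minus Pielou's evenness);
* Jaccard overlap `|A∩B| / |A∪B|` of receptor sets, and Spearman/Pearson
  correlation of abundances over shared receptors;
* occurrence classes: the number of PBMC time points n at which each
  receptor is observed, with persistent = n = T; classes compared by
  two-sided Mann–Whitney U on abundance and nucleotide redundancy (distinct
  CDR3 nucleotide sequences per receptor);
* a similarity network joining receptors whose CDR3s are within one
  Levenshtein edit, with a degree-vs-persistence trend tested by shuffling
  occurrence counts across nodes (p with the add-one convention);
* clonal cohorts: receptors in the per-sample top 1% at least twice,
  median-imputed trajectories, a correlation graph at threshold 0.95, and
  its maximum clique, with significance from per-receptor label shuffles;
* publicness: share-fraction deciles against an external cohort (N = 778 by
  default), and enrichment of persistent receptors among highly public ones
  (share fraction > 0.70) by t-test across individuals plus per-individual
  permutation tests.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

```python
import tcrpersist as tp

# simulate a 3-individual, 8-time-point cohort with known ground truth
cfg = tp.SimConfig(seed=1, pool_size=8000, depth=100_000)
pool = tp.generate_truth(cfg)
series = tp.draw_cohort(pool, seed=2)
sharing = tp.truth_sharing_table(pool)

ts = series["01"]
profile = tp.occurrence_profile(ts)
persistent = tp.persistent_set(profile)
print(f"unique receptors: {len(profile.counts)}")
print(f"persistent: {len(persistent)} "
      f"({100 * len(persistent) / len(profile.counts):.2f}% of unique)")

summary = tp.occurrence_class_summary(ts, profile)
print(f"memory overlap of persistent class: "
      f"{summary.table.loc[8, 'memory_overlap_fraction']:.3f}")

graph = tp.build_similarity_graph(profile.counts, d_max=1)
bins = tp.neighbor_decile_bins(graph)
p = tp.connectivity_permutation_test(bins, profile, n_perm=2000, seed=3)
print(f"connectivity-persistence permutation p: {p:.5f}")
```

Output:

```
unique receptors: 3784
persistent: 135 (3.57% of unique)
memory overlap of persistent class: 0.970
connectivity-persistence permutation p: 0.00050
```

Of ~3800 receptors observed across one individual's year, ~3.6% are present
at every draw; nearly all of those also appear in the sorted memory
compartment, and receptors with more sequence-similar neighbors persist
across more time points than a shuffled null allows (the smallest p
attainable at 2000 shuffles is 1/2001 ≈ 0.0005).

The same analysis runs from the shell on a YAML configuration (either a
`simulate:` block or a `manifest:` of clonotype TSVs):

```sh
tcrpersist run --config run.yaml --seed 1 --outdir results/run
```

which writes per-sample summary statistics, the Jaccard matrix, occurrence
class tables with Mann–Whitney comparisons, network bin tables and edge
lists, cohort reports, and publicness enrichment, all as TSV/JSON.

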