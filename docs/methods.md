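# Methods

`tcrpersist` analyses longitudinal TCRβ repertoires: tab-delimited clonotype
tables from repeated blood draws of the same individuals, optionally with
flow-sorted memory (CD45RO+) and naive (CD45RA+) libraries, plus an external
cohort sharing table. This note records the model and procedure, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Receptor and clone model

A **clone** is a unique (V gene, J gene, CDR3 nucleotide sequence) — the
resolution of a T-cell lineage. A **receptor** (TCRβ) is a unique
(V gene, CDR3 amino-acid sequence, J gene); several clones may encode one
receptor, and that count is its **nucleotide redundancy**, a signature of
convergent recombination. Gene labels are compared verbatim: no allele or
family collapsing is applied, which may split identities relative to
analyses that normalize labels (an open point documented here because no
normalization rule is universal across exports).

A row is **productive** when its CDR3 carries no stop codon and both V and J
resolved (labels `""`, `unresolved`, `unknown`, `na`, `(undefined)` count as
unresolved). Nonproductive rows are retained: every relative abundance uses
the total template count of the sample — productive plus nonproductive — as
its denominator, because nonproductive rearrangements are part of the
sequenced DNA pool. Consequently productive abundances sum to the
productive fraction (< 1), and all downstream statistics renormalize within
the productive set where a distribution over receptors is needed (entropy,
evenness).

## Summary statistics

* **Overlap**: Jaccard index of productive receptor sets (not
  abundance-weighted).
* **Diversity**: Shannon estimate `exp(H)` with `H = −Σ p_i ln p_i` in nats,
  so the estimate inverts the entropy exactly and reads as an effective
  receptor number.
* **Clonality**: `1 − H/ln S` (one minus Pielou's evenness). Same log base
  as the entropy, making the quantity base-free; defined as 0 at `S = 1`
  (the evenness limit), so degenerate tiny samples do not crash.
* **Abundance correlations**: Spearman (or Pearson) over the intersection of
  receptor keys only, with the intersection size reported.
* **High-abundance subset**: the `ceil(f·S)` most abundant receptors per
  sample (`f = 0.01` by default); ties at the cutoff break on the
  lexicographic receptor key so the subset is deterministic.
* **Rarefaction**: without-replacement (multivariate hypergeometric)
  subsampling of templates, 10 replicates by default; at full depth the
  curve equals observed richness exactly.

## Persistence

A receptor is **persistent** in an individual when it is detected in every
PBMC time point; sorted compartments never contribute to the occurrence
count. Occurrence classes `n = 1..T` are profiled by: member count; mean
abundance (averaging only over samples where the receptor is present —
zero-filling would conflate prevalence with abundance); mean nucleotide
redundancy (distinct CDR3 nucleotide sequences across the whole PBMC
series); overlap with the *union* of the sorted memory (resp. naive)
libraries (per-time-point overlap is not distinguishable from pooled overlap
in the source data, so the pooled choice is documented rather than assumed);
and the fraction of each sample's productive abundance held by the class.
When no sorted libraries exist the overlap fields are absent (NaN), not
zero. Class pairs are compared by two-sided Mann-Whitney U (exact null for
small tie-free samples, normal approximation with continuity correction
otherwise), reporting U of the lower-occupancy class.

Persistence detection is threshold-free but abundance-censored: a clone
whose frequency sits below ~1/depth at any draw will be missed. The
recovery guarantee quoted by the tests is therefore conditional: truth
persistent clones whose worst-time-point relative abundance is at least
10/depth are recovered with sensitivity ≥ 0.95, and truth-transient clones
are never called persistent (they cannot appear at all T points by
construction).

## CDR3 similarity network

Nodes are unique receptors; an edge joins receptors whose CDR3 amino-acid
sequences are within `d_max` Levenshtein edits (default 1; identical CDR3s
with different V/J are distinct nodes at distance 0). V/J matching for edges
is off by default and available as `network.same_vj`, since near-identical
CDR3s are the standard proxy for shared antigen specificity and the edge
rule is exposed in output metadata. Distances come from `edlib` (unit-cost,
with a banded cutoff); for `d_max = 1` candidate pairs come from a
symmetric-deletion index, with every candidate verified exactly, so graph
construction equals all-pairs thresholding (property-tested against a naive
oracle).

Nodes are binned by degree into deciles of the maximum observed degree
(`bin = min(10·d // d_max_observed, 9)`). The association between
connectivity and persistence is summarized by the Spearman correlation
between node degree and occurrence count, computed on nodes, not on bins —
the binning is retained for display, but a bin-level statistic would discard
within-bin variation and depend on an arbitrary bin count. Significance
comes from shuffling occurrence counts across nodes with the graph held
fixed (default 10,000 shuffles), with the add-one convention
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`.

## Clonal cohorts

Candidates are receptors in the per-sample top 1% in at least two PBMC
samples (expanded clones). Their trajectory matrix over PBMC time points
imputes absences with the sample's median productive receptor abundance —
the median over *all* of the sample's receptors, not just candidates,
because an undetected receptor is best guessed to be about as abundant as a
typical detected one. Pairs correlating above 0.95 (strict; both Spearman
and Pearson are run and reported separately) form a graph whose maximum
clique is the reported cohort; clique search enumerates maximal cliques
exactly (the candidate sets are small), breaking ties toward the
lexicographically smallest member set. Significance re-runs the entire
construction (imputation → correlation graph → maximum clique) on datasets
in which each candidate's values are independently permuted across sample
labels (default 1000 shuffles). Members are flagged as possible sequencing
artifacts when their mean abundance is under 10% of the cohort's dominant
member and their CDR3 is within 2 edits of it.

Two caveats, measured during design and relevant to interpreting cohort
p-values anywhere this method is used:

1. **Autocorrelation**: trajectories with temporal structure (random walks)
   correlate spuriously even between independent clones; the label
   permutation destroys that structure, so the test is anti-conservative
   against a "independent but smooth" null.
2. **Compositional coupling**: frequencies within a sample sum to one, so a
   dominant clone's sampling fluctuation moves every other frequency; at
   high clonality this inflates observed correlations relative to the
   permuted null.

3. **Discreteness**: the clique size takes only a few integer values under
   the null, so its permutation p-value is valid but conservative, with
   large atoms — it is *not* uniformly distributed under the null and should
   not be treated as a continuous p.

## Publicness

The sharing table maps receptors to the number of subjects in an external
reference cohort carrying them; receptors absent from the table count as
shared by zero subjects (the table enumerates observed receptors, and
absence is informative privacy; configurable). Share fraction deciles use
`bin = min(⌊10f⌋, 9)` with `f = 1` clamped into the top bin. "Highly
public" means share fraction strictly above 0.70 — at a cohort of 778 the
boundary sits between 544 (0.6992, excluded) and 545 (0.7005, included).
Enrichment of persistent receptors among highly public ones is tested two
ways: an independent two-sample t-test across individuals on highly-public
counts in the persistent versus single-occurrence sets (counts, not
fractions), and a per-individual permutation test shuffling occurrence
counts across receptors (default 10,000 shuffles; the count statistic is
discrete, so the same conservativeness caveat as above applies). The
receptor universe entering the binning is the per-individual union by
default (an intersection option exists), echoed in output metadata.

## Synthetic cohorts

The generator emulates the study design end to end so every stage is
testable against known labels: `n_individuals = 3`, eight PBMC time points
at months (0, 1, 2, 3, 5, 6, 7, 12), sorted memory/naive libraries at
months 5–7, and an external cohort of size 778.

* **Clone-size law**: log-normal base abundances (σ = 2.5). This reproduces
  the unimodal log-frequency shape of deep repertoires (modal relative
  abundance near 10⁻⁶ at study-scale depth) and is trivially sampled; no
  explicit power law is asserted.
* **Persistence classes**: 1% persistent (positive abundance at every time
  point, 10× abundance boost), 9% intermittent (present at a random subset
  of 2..T−1 points), the rest transient (present exactly once). The boost
  encodes the observation that receptors maintained across time are also
  more abundant; with the boost disabled the class abundance distributions
  are statistically indistinguishable (tested).
* **Temporal model**: per-clone geometric random walk (σ = 0.4 per step) by
  default. An iid log-normal multiplier model (`trajectory_model: iid`) is
  provided for permutation-null calibration, where exchangeability across
  time points is required — random walks are not exchangeable and correlate
  spuriously (see cohort caveats above).
* **Nucleotide redundancy**: `1 + Poisson(λ)` distinct codon-randomized
  nucleotide sequences per receptor, λ = 0.5 for persistent vs 0.05
  otherwise — matching the direction of the convergent-recombination
  signal without asserting magnitudes.
* **Compartments**: P(memory flag) = 0.98 for persistent clones and 0.4
  otherwise; memory libraries draw only from flagged clones, naive from the
  complement. These are tunable emulation defaults, not biological claims.
* **Publicness**: 10% of each pool is drawn from a global public pool shared
  across individuals, with share counts spanning all deciles but heavily
  skewed toward near-private sharing; highly public entries (f > 0.7) are
  persistent with probability 0.9 in each individual (`coupling = 0`
  decouples them for null runs).
* **Planted structure**: 40 sequence-similarity clusters (a persistent seed
  plus 3 single-substitution variants, mostly persistent) exercise the
  network stage; one planted 10-member cohort shares a latent iid log-normal
  trajectory (σ = 1.0) with idiosyncratic noise at 1/20 of the latent sd.
  The noise ratio is set by the edge threshold: with latent:noise variance
  ratio r the expected pairwise trajectory correlation is r/(r+1), so any
  ratio below 19:1 would put the cohort *under* the 0.95 cutoff by
  construction; 400:1 leaves headroom for sampling noise and rank
  discreteness over 8 points. Cohort members are placed in the 99.6–99.99th
  percentile band of the clone-size law so they rank in each sample's
  high-abundance fraction.
* **Sampling**: multinomial draws of `depth` templates (default 10⁵) from
  trajectory-adjusted abundances, with nonproductive templates injected at a
  fixed fraction (0.15, a typical order for genomic-DNA immunosequencing
  exports). Identical seeds give byte-identical TSVs.

What the generator does **not** emulate: V(D)J junctional sequence
statistics and generation probabilities (CDR3s are random strings over the
amino-acid alphabet with study-like lengths), PCR amplification bias,
sequencing error (reads are exact), time-varying diversity regulation, and
any HLA or antigen structure behind publicness. Passing tests therefore
demonstrate that the statistics recover planted abundance/persistence/
sharing structure through realistic undersampling — not that real
repertoires contain such structure.

## Problem sizes and tolerances

Test and acceptance runs use scaled-down cohorts — pools of 2×10³–2×10⁴
clones at depths of 3×10⁴–10⁵ templates — chosen so observed per-sample
diversity (~1.5–6×10³ receptors) is undersampled relative to the pool, as
in the study, while the full suite stays desk-sized. At this diversity a
literal top-1% subset holds only ~16 receptors, so the high-abundance
parallel re-analysis in the qualitative checks uses the top 5% to obtain a
subset of comparable relative size. Closed-form statistic checks use 10⁻⁴
tolerances; conservation and normalization invariants use 10⁻⁹; frequency
closure after reading uses 10⁻⁶. Null-calibration runs regenerate the truth
pool each replicate, since quantities such as the persistent × highly-public
overlap are realized once per pool.

## Known limitations

* Persistence is relative to the detection limit: "persistent above
  sampling depth" is the honest reading of every persistent set.
* The cohort permutation test inherits the caveats listed above
  (autocorrelation, compositional coupling, discreteness); its p-values are
  evidence against exchangeability, not a calibrated continuous scale.
* Verbatim gene labels may split receptor identities across export dialects
  that resolve alleles differently.
* The t-test across three individuals has two degrees of freedom; the
  per-individual permutation test is the primary enrichment evidence.
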