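"""Synthetic longitudinal TCR-beta repertoires with known ground truth.

The generator emulates the structure of a multi-individual blood time
course: several individuals, each with a clone pool whose base abundances
are heavy-tailed (log-normal), a persistent subset with boosted abundance
and elevated nucleotide redundancy, intermittent and transient clones,
public clones shared across individuals with cohort share counts spanning
all publicness deciles, flow-sortable memory/naive compartment membership, a
nonproductive read fraction, and multinomial blood-draw undersampling at a
configurable template depth.

Every downstream module can therefore be tested against known labels:
persistence classes, planted co-trajectory cohorts, planted
sequence-similarity clusters, and the truth sharing table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .publicness import SharingTable
from .types import (
    CloneRecord,
    Compartment,
    RepertoireSample,
    TcrBeta,
    TimeSeriesRepertoire,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid (standard genetic code), for reverse-translating CDR3s
_CODONS: dict[str, list[str]] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _codon = _c1 + _c2 + _c3
            _aa = {
                "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
                "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
                "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
                "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
                "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
                "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
                "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
                "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
                "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
                "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
                "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
                "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
                "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
                "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
                "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
                "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
            }[_codon]
            _CODONS.setdefault(_aa, []).append(_codon)

V_GENES = [f"TCRBV{i:02d}-01" for i in (2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13,
                                        14, 15, 16, 18, 19, 20, 24, 25, 27, 28, 29, 30)]
J_GENES = [f"TCRBJ01-{i:02d}" for i in range(1, 7)] + [
    f"TCRBJ02-{i:02d}" for i in range(1, 8)
]

PERSISTENT = "persistent"
INTERMITTENT = "intermittent"
TRANSIENT = "transient"


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study design this package targets — 3 individuals,
    8 PBMC time points over a year (months 0,1,2,3,5,6,7,12) with sorted
    memory/naive libraries at months 5,6,7 — at a computationally friendly
    pool size and sequencing depth.
    """

    seed: int
    n_individuals: int = 3
    n_timepoints: int = 8
    time_points: tuple[int, ...] = (0, 1, 2, 3, 5, 6, 7, 12)
    sorted_time_points: tuple[int, ...] = (5, 6, 7)
    pool_size: int = 20_000
    depth: int = 100_000
    lognormal_sigma: float = 2.5
    persistent_fraction: float = 0.01
    intermittent_fraction: float = 0.09
    abundance_boost: float = 10.0
    trajectory_sigma: float = 0.4
    trajectory_model: str = "walk"  # "walk" (geometric random walk) or "iid"
    nt_redundancy_lambda_persistent: float = 0.5
    nt_redundancy_lambda_other: float = 0.05
    nonproductive_fraction: float = 0.15
    cohort_size: int = 778
    public_fraction: float = 0.10
    #: probability mass per publicness decile for public-clone share counts;
    #: heavily skewed toward near-private sharing, but spanning every decile
    share_decile_weights: tuple[float, ...] = (
        0.55, 0.09, 0.06, 0.05, 0.04, 0.04, 0.04, 0.04, 0.04, 0.05,
    )
    public_persistence_coupling: float = 0.9
    p_memory_persistent: float = 0.98
    p_memory_other: float = 0.4
    n_similarity_clusters: int = 40
    similarity_cluster_size: int = 4
    n_planted_cohorts: int = 1
    planted_cohort_size: int = 10
    cohort_quantile_range: tuple[float, float] = (0.996, 0.9999)
    cohort_latent_sigma: float = 1.0
    cohort_noise_sd_ratio: float = 20.0

    def __post_init__(self) -> None:
        fracs = {
            "persistent_fraction": self.persistent_fraction,
            "intermittent_fraction": self.intermittent_fraction,
            "nonproductive_fraction": self.nonproductive_fraction,
            "public_fraction": self.public_fraction,
            "public_persistence_coupling": self.public_persistence_coupling,
            "p_memory_persistent": self.p_memory_persistent,
            "p_memory_other": self.p_memory_other,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1:
            raise SimConfigError("depth must be >= 1")
        if self.n_timepoints != len(self.time_points):
            raise SimConfigError("time_points length must equal n_timepoints")
        if 0 < self.persistent_fraction * self.pool_size < 1:
            raise SimConfigError(
                "persistent_fraction x pool_size < 1: no persistent clone can exist"
            )
        if self.persistent_fraction + self.intermittent_fraction > 1:
            raise SimConfigError("class fractions exceed 1")


@dataclass(slots=True)
class IndividualTruth:
    """Ground-truth clone pool of one individual (parallel arrays)."""

    individual_id: str
    tcrs: list[TcrBeta]
    nt_variants: list[tuple[str, ...]]
    nt_props: list[np.ndarray]
    base_abundance: np.ndarray
    persistence_class: np.ndarray  # str array
    memory_flag: np.ndarray  # bool
    share_count: np.ndarray  # int
    trajectory: np.ndarray  # (n_clones, T) multipliers, 0 = truly absent
    cohort_id: np.ndarray  # int, -1 = none
    cluster_id: np.ndarray  # int, -1 = none
    nonproductive_rows: list[tuple[str, str, str, str]]  # (aa, v, j, nt)
    nonproductive_base: np.ndarray
    # flattened nucleotide-variant units for multinomial draws
    unit_clone: np.ndarray = field(default=None)  # type: ignore[assignment]
    unit_nt: list[str] = field(default_factory=list)
    unit_prop: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        clone_idx, props, nts = [], [], []
        for i, (variants, p) in enumerate(zip(self.nt_variants, self.nt_props)):
            for v, pr in zip(variants, p):
                clone_idx.append(i)
                nts.append(v)
                props.append(pr)
        self.unit_clone = np.asarray(clone_idx, dtype=np.int64)
        self.unit_nt = nts
        self.unit_prop = np.asarray(props, dtype=float)

    @property
    def n_clones(self) -> int:
        return len(self.tcrs)


@dataclass(slots=True)
class TruthClonePool:
    """Ground truth for a whole synthetic cohort."""

    config: SimConfig
    individuals: dict[str, IndividualTruth]

    @property
    def individual_ids(self) -> list[str]:
        return list(self.individuals)


def _random_cdr3(rng: np.random.Generator, length: int | None = None) -> str:
    if length is None:
        length = int(np.clip(round(rng.normal(14.5, 1.8)), 8, 20))
    middle = "".join(rng.choice(list(AMINO_ACIDS), size=length - 2))
    return "C" + middle + "F"


def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[c][rng.integers(len(_CODONS[c]))] for c in aa)


def _share_counts(
    rng: np.random.Generator, n: int, cohort_size: int, weights
) -> np.ndarray:
    """Share counts spanning all publicness deciles, skewed toward private."""
    decile_weights = np.asarray(weights, dtype=float)
    decile_weights = decile_weights / decile_weights.sum()
    deciles = rng.choice(10, size=n, p=decile_weights)
    fracs = (deciles + rng.random(n)) / 10.0
    return np.clip(np.round(fracs * cohort_size), 1, cohort_size).astype(int)


def _assign_classes(rng, n, cfg: SimConfig) -> np.ndarray:
    u = rng.random(n)
    classes = np.full(n, TRANSIENT, dtype=object)
    classes[u < cfg.persistent_fraction] = PERSISTENT
    classes[(u >= cfg.persistent_fraction)
            & (u < cfg.persistent_fraction + cfg.intermittent_fraction)] = INTERMITTENT
    return classes


def _trajectories(rng, classes: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Per-clone per-timepoint abundance multipliers.

    Persistent clones follow the temporal model (geometric random walk by
    default, or iid log-normal multipliers — exchangeable across time, the
    null used for permutation-test calibration); intermittent clones are
    present in a random subset of 2..T-1 time points; transient clones
    appear exactly once.
    """
    n, t = len(classes), cfg.n_timepoints
    traj = np.zeros((n, t))
    steps = rng.normal(0.0, cfg.trajectory_sigma, size=(n, t))
    if cfg.trajectory_model == "iid":
        walk = np.exp(steps)
    elif cfg.trajectory_model == "walk":
        walk = np.exp(np.cumsum(steps, axis=1))
    else:
        raise SimConfigError(f"unknown trajectory_model {cfg.trajectory_model!r}")
    for i, cls in enumerate(classes):
        if cls == PERSISTENT:
            traj[i] = walk[i]
        elif cls == INTERMITTENT:
            k = rng.integers(2, t) if t > 2 else min(2, t)
            idx = rng.choice(t, size=k, replace=False)
            traj[i, idx] = walk[i, idx]
        else:
            traj[i, rng.integers(t)] = walk[i, rng.integers(t)]
    return traj


def generate_truth(config: SimConfig) -> TruthClonePool:
    """Deterministically generate the ground-truth clone pools.

    The same seed yields identical pools.  Persistent clones receive an
    abundance boost and a stochastically larger nucleotide-redundancy
    distribution than transient clones; a configurable fraction of clones is
    shared across individuals with share counts spanning all publicness
    deciles; highly public clones (share fraction > 0.7) are persistent with
    probability ``public_persistence_coupling`` in each individual.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    used_cdr3: set[str] = set()

    def fresh_cdr3() -> str:
        while True:
            s = _random_cdr3(rng)
            if s not in used_cdr3:
                used_cdr3.add(s)
                return s

    def fresh_tcr() -> TcrBeta:
        return TcrBeta(
            v_gene=V_GENES[rng.integers(len(V_GENES))],
            cdr3_aa=fresh_cdr3(),
            j_gene=J_GENES[rng.integers(len(J_GENES))],
        )

    # shared public pool: same receptors and share counts for every individual
    n_public = int(round(cfg.public_fraction * cfg.pool_size))
    public_tcrs = [fresh_tcr() for _ in range(n_public)]
    public_counts = _share_counts(rng, n_public, cfg.cohort_size,
                                  cfg.share_decile_weights)

    individuals: dict[str, IndividualTruth] = {}
    for k in range(cfg.n_individuals):
        ind_id = f"{k + 1:02d}"
        tcrs = list(public_tcrs)
        share = list(public_counts)
        for _ in range(cfg.pool_size - n_public):
            tcrs.append(fresh_tcr())
            share.append(0)

        classes = _assign_classes(rng, len(tcrs), cfg)
        # couple high publicness to persistence (moot when no clone may persist)
        if cfg.public_persistence_coupling > 0 and cfg.persistent_fraction > 0:
            for i in range(n_public):
                if share[i] / cfg.cohort_size > 0.7 and (
                    rng.random() < cfg.public_persistence_coupling
                ):
                    classes[i] = PERSISTENT

        base = rng.lognormal(0.0, cfg.lognormal_sigma, size=len(tcrs))
        base[classes == PERSISTENT] *= cfg.abundance_boost
        cluster_id = np.full(len(tcrs), -1, dtype=int)
        cohort_id = np.full(len(tcrs), -1, dtype=int)

        # planted sequence-similarity clusters around persistent seeds
        pers_idx = np.flatnonzero(classes == PERSISTENT)
        n_seeds = min(cfg.n_similarity_clusters, len(pers_idx))
        seeds = rng.choice(pers_idx, size=n_seeds, replace=False) if n_seeds else []
        extra_tcrs, extra_class, extra_cluster = [], [], []
        for c, si in enumerate(seeds):
            cluster_id[si] = c
            seed_cdr3 = tcrs[si].cdr3_aa
            for _ in range(cfg.similarity_cluster_size - 1):
                for _attempt in range(50):
                    pos = rng.integers(1, len(seed_cdr3) - 1)
                    sub = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                    variant = seed_cdr3[:pos] + sub + seed_cdr3[pos + 1 :]
                    if variant != seed_cdr3 and variant not in used_cdr3:
                        used_cdr3.add(variant)
                        break
                else:  # pragma: no cover - overwhelmingly unlikely
                    variant = fresh_cdr3()
                extra_tcrs.append(
                    TcrBeta(tcrs[si].v_gene, variant, tcrs[si].j_gene)
                )
                extra_class.append(
                    PERSISTENT if rng.random() < 0.8 else INTERMITTENT
                )
                extra_cluster.append(c)
        for t_, cl_, cu_ in zip(extra_tcrs, extra_class, extra_cluster):
            tcrs.append(t_)
            share.append(0)
        classes = np.concatenate([classes, np.array(extra_class, dtype=object)])
        b_extra = rng.lognormal(0.0, cfg.lognormal_sigma, size=len(extra_tcrs))
        b_extra[np.array(extra_class, dtype=object) == PERSISTENT] *= cfg.abundance_boost
        base = np.concatenate([base, b_extra])
        cluster_id = np.concatenate([cluster_id, np.array(extra_cluster, dtype=int)])
        cohort_id = np.concatenate([cohort_id, np.full(len(extra_tcrs), -1, dtype=int)])

        # planted co-trajectory cohorts: new high-abundance persistent clones
        # placed in the upper quantile band of the clone-size law so they rank
        # in each sample's top abundance fraction (spanning a range of sizes)
        n_cohort_members = cfg.n_planted_cohorts * cfg.planted_cohort_size
        co_tcrs = [fresh_tcr() for _ in range(n_cohort_members)]
        co_ids = np.repeat(np.arange(cfg.n_planted_cohorts), cfg.planted_cohort_size)
        from scipy.stats import norm as _norm

        q_lo, q_hi = cfg.cohort_quantile_range
        q = rng.uniform(q_lo, q_hi, size=n_cohort_members)
        co_base = np.exp(cfg.lognormal_sigma * _norm.ppf(q)) * cfg.abundance_boost
        tcrs.extend(co_tcrs)
        share.extend([0] * n_cohort_members)
        classes = np.concatenate([classes, np.full(n_cohort_members, PERSISTENT, dtype=object)])
        base = np.concatenate([base, co_base])
        cluster_id = np.concatenate([cluster_id, np.full(n_cohort_members, -1, dtype=int)])
        cohort_id = np.concatenate([cohort_id, co_ids])

        traj = _trajectories(rng, classes, cfg)
        # overwrite planted cohort trajectories with a shared latent path
        for c in range(cfg.n_planted_cohorts):
            members = np.flatnonzero(cohort_id == c)
            latent = rng.normal(0.0, cfg.cohort_latent_sigma, size=cfg.n_timepoints)
            noise_sd = cfg.cohort_latent_sigma / cfg.cohort_noise_sd_ratio
            eps = rng.normal(0.0, noise_sd, size=(len(members), cfg.n_timepoints))
            traj[members] = np.exp(latent[None, :] + eps)

        # nucleotide redundancy: 1 + Poisson(lambda), larger for persistent
        lam = np.where(
            classes == PERSISTENT,
            cfg.nt_redundancy_lambda_persistent,
            cfg.nt_redundancy_lambda_other,
        )
        redundancy = 1 + rng.poisson(lam.astype(float))
        nt_variants, nt_props = [], []
        for i, tcr in enumerate(tcrs):
            variants: set[str] = set()
            while len(variants) < redundancy[i]:
                variants.add(_reverse_translate(tcr.cdr3_aa, rng))
            variants = tuple(sorted(variants))
            props = rng.dirichlet(np.ones(len(variants))) if len(variants) > 1 else np.ones(1)
            nt_variants.append(variants)
            nt_props.append(props)

        p_mem = np.where(classes == PERSISTENT, cfg.p_memory_persistent, cfg.p_memory_other)
        memory = rng.random(len(tcrs)) < p_mem

        # nonproductive pool: stop-codon CDR3s with their own abundances
        n_np = int(round(0.1 * cfg.pool_size))
        np_rows = []
        for _ in range(n_np):
            aa = _random_cdr3(rng)
            pos = rng.integers(1, len(aa) - 1)
            aa = aa[:pos] + "*" + aa[pos + 1 :]
            np_rows.append(
                (
                    aa,
                    V_GENES[rng.integers(len(V_GENES))],
                    J_GENES[rng.integers(len(J_GENES))],
                    _reverse_translate(aa.replace("*", "W"), rng),
                )
            )
        np_base = rng.lognormal(0.0, cfg.lognormal_sigma, size=n_np)

        individuals[ind_id] = IndividualTruth(
            individual_id=ind_id,
            tcrs=tcrs,
            nt_variants=nt_variants,
            nt_props=nt_props,
            base_abundance=base,
            persistence_class=classes,
            memory_flag=memory,
            share_count=np.asarray(share, dtype=int),
            trajectory=traj,
            cohort_id=cohort_id,
            cluster_id=cluster_id,
            nonproductive_rows=np_rows,
            nonproductive_base=np_base,
        )
    return TruthClonePool(config=cfg, individuals=individuals)


def draw_sample(
    pool: TruthClonePool,
    individual_id: str,
    time_point: int,
    compartment: Compartment | str = Compartment.PBMC,
    depth: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RepertoireSample:
    """Multinomial blood-draw undersampling of one library.

    Template counts are drawn multinomially from trajectory-adjusted clone
    abundances; nonproductive templates are injected at the configured
    fraction.  The memory compartment draws only from memory-flagged clones,
    the naive compartment from their complement.  Identical seeds give
    identical samples.
    """
    compartment = Compartment(compartment)
    cfg = pool.config
    if individual_id not in pool.individuals:
        raise KeyError(f"unknown individual {individual_id!r}")
    truth = pool.individuals[individual_id]
    if time_point not in cfg.time_points:
        raise KeyError(f"unknown time point {time_point!r}")
    t = cfg.time_points.index(time_point)
    depth = cfg.depth if depth is None else int(depth)
    if rng is None:
        rng = np.random.default_rng(seed)

    w_clone = truth.base_abundance * truth.trajectory[:, t]
    if compartment is Compartment.MEMORY:
        w_clone = w_clone * truth.memory_flag
    elif compartment is Compartment.NAIVE:
        w_clone = w_clone * ~truth.memory_flag

    w_units = w_clone[truth.unit_clone] * truth.unit_prop
    prod_mass = w_units.sum()
    np_mass = truth.nonproductive_base.sum()
    npf = cfg.nonproductive_fraction
    probs = np.concatenate(
        [
            (1.0 - npf) * w_units / prod_mass if prod_mass > 0 else np.zeros_like(w_units),
            npf * truth.nonproductive_base / np_mass if np_mass > 0 else np.zeros(0),
        ]
    )
    probs = probs / probs.sum()
    counts = rng.multinomial(depth, probs)

    records: list[CloneRecord] = []
    n_units = len(w_units)
    for u in np.flatnonzero(counts[:n_units]):
        ci = truth.unit_clone[u]
        tcr = truth.tcrs[ci]
        records.append(
            CloneRecord(
                cdr3_aa=tcr.cdr3_aa,
                v_gene=tcr.v_gene,
                j_gene=tcr.j_gene,
                cdr3_nt=truth.unit_nt[u],
                count=int(counts[u]),
                frequency=counts[u] / depth,
                productive=True,
            )
        )
    for i in np.flatnonzero(counts[n_units:]):
        aa, v, j, nt = truth.nonproductive_rows[i]
        records.append(
            CloneRecord(
                cdr3_aa=aa,
                v_gene=v,
                j_gene=j,
                cdr3_nt=nt,
                count=int(counts[n_units + i]),
                frequency=counts[n_units + i] / depth,
                productive=False,
            )
        )
    sample = RepertoireSample(individual_id, int(time_point), compartment, records)
    sample.validate()
    return sample


def _derived_seed(seed: int, *salts: int) -> int:
    """Deterministic per-stage sub-seed, kept below 2**31."""
    h = 2166136261
    for x in (seed, *salts):
        h = (h ^ (x + 0x9E3779B9)) * 16777619 % (2**31)
    return int(h)


def draw_time_series(
    pool: TruthClonePool,
    individual_id: str,
    depth: int | None = None,
    seed: int | None = None,
    sorted_compartments: bool = True,
) -> TimeSeriesRepertoire:
    """Draw the full longitudinal design for one individual."""
    cfg = pool.config
    base_seed = cfg.seed if seed is None else seed
    ind_salt = int(individual_id)
    pbmc = [
        draw_sample(
            pool, individual_id, tp, Compartment.PBMC, depth,
            seed=_derived_seed(base_seed, ind_salt, ti, 0),
        )
        for ti, tp in enumerate(cfg.time_points)
    ]
    memory, naive = [], []
    if sorted_compartments:
        for ti, tp in enumerate(cfg.time_points):
            if tp in cfg.sorted_time_points:
                memory.append(
                    draw_sample(pool, individual_id, tp, Compartment.MEMORY, depth,
                                seed=_derived_seed(base_seed, ind_salt, ti, 1))
                )
                naive.append(
                    draw_sample(pool, individual_id, tp, Compartment.NAIVE, depth,
                                seed=_derived_seed(base_seed, ind_salt, ti, 2))
                )
    return TimeSeriesRepertoire(individual_id, pbmc, memory, naive)


def draw_cohort(
    pool: TruthClonePool,
    depth: int | None = None,
    seed: int | None = None,
    sorted_compartments: bool = True,
) -> dict[str, TimeSeriesRepertoire]:
    """Time series for every individual in the pool."""
    return {
        ind: draw_time_series(pool, ind, depth, seed, sorted_compartments)
        for ind in pool.individual_ids
    }


def truth_sharing_table(pool: TruthClonePool, cohort_size: int | None = None) -> SharingTable:
    """Expose every clone's ground-truth cohort share count as a SharingTable."""
    size = pool.config.cohort_size if cohort_size is None else cohort_size
    counts: dict[TcrBeta, int] = {}
    for truth in pool.individuals.values():
        for tcr, c in zip(truth.tcrs, truth.share_count):
            counts[tcr] = int(c)
    return SharingTable(cohort_size=size, counts=counts)


def write_truth_labels(pool: TruthClonePool, path) -> None:
    """Per-clone truth labels as TSV (test-harness interface)."""
    lines = [
        "individual\taminoAcid\tvGeneName\tjGeneName\tpersistence_class\t"
        "memory_flag\tshare_count\tcohort_id\tcluster_id\tbase_abundance"
    ]
    for ind, truth in pool.individuals.items():
        for i, tcr in enumerate(truth.tcrs):
            lines.append(
                f"{ind}\t{tcr.cdr3_aa}\t{tcr.v_gene}\t{tcr.j_gene}\t"
                f"{truth.persistence_class[i]}\t{int(truth.memory_flag[i])}\t"
                f"{truth.share_count[i]}\t{truth.cohort_id[i]}\t"
                f"{truth.cluster_id[i]}\t{truth.base_abundance[i]:.9g}"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
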