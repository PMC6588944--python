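"""Core domain types for TCR-beta repertoire analysis.

The analysis unit is the TCR-beta receptor, identified by the exact triple
(V gene, CDR3 amino-acid sequence, J gene).  A *clone* is finer-grained: it
additionally carries the CDR3 nucleotide sequence, so several clones (distinct
nucleotide rearrangements) may encode the same receptor — this "nucleotide
redundancy" is a signature of convergent recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

STOP_SYMBOL = "*"

#: V/J labels treated as "did not map to a gene" (case-insensitive).
UNRESOLVED_GENE_LABELS = frozenset({"", "unresolved", "unknown", "na", "(undefined)"})


def gene_is_resolved(label: str) -> bool:
    """True when a V/J gene label counts as successfully assigned."""
    return label.strip().lower() not in UNRESOLVED_GENE_LABELS


@dataclass(frozen=True, slots=True)
class TcrBeta:
    """A unique receptor: V gene + CDR3 amino acids + J gene.

    Equality and hashing are over the exact string triple and nothing else;
    gene labels are used verbatim (no allele collapsing).
    """

    v_gene: str
    cdr3_aa: str
    j_gene: str

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if STOP_SYMBOL in self.cdr3_aa:
            raise ValueError(f"cdr3_aa contains a stop symbol: {self.cdr3_aa!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        """Deterministic sort key (used wherever ties must break reproducibly)."""
        return (self.cdr3_aa, self.v_gene, self.j_gene)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.v_gene}|{self.cdr3_aa}|{self.j_gene}"


class Compartment(str, Enum):
    """Cell compartment a sequencing library was drawn from."""

    PBMC = "PBMC"
    MEMORY = "memory"
    NAIVE = "naive"


@dataclass(frozen=True, slots=True)
class CloneRecord:
    """One nucleotide-level clone row of a repertoire sample.

    ``frequency`` is the clone's share of *all* template counts in the sample,
    productive and nonproductive alike — nonproductive rearrangements are part
    of the sequenced pool, so they stay in the denominator.
    """

    cdr3_aa: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    count: int
    frequency: float
    productive: bool

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError(f"count must be a non-negative integer, got {self.count!r}")

    @property
    def tcr(self) -> Optional[TcrBeta]:
        """The receptor identity, or None for nonproductive records."""
        if not self.productive:
            return None
        return TcrBeta(self.v_gene, self.cdr3_aa, self.j_gene)

    @property
    def clone_key(self) -> tuple[str, str, str, str]:
        return (self.cdr3_aa, self.v_gene, self.j_gene, self.cdr3_nt)


def is_productive(cdr3_aa: str, v_gene: str, j_gene: str) -> bool:
    """Productive = no stop codon in the CDR3 and both V and J resolved."""
    if not cdr3_aa or STOP_SYMBOL in cdr3_aa:
        return False
    return gene_is_resolved(v_gene) and gene_is_resolved(j_gene)


FREQUENCY_SUM_TOL = 1e-6


@dataclass(slots=True)
class RepertoireSample:
    """One sequencing library: an individual at a time point in a compartment."""

    individual_id: str
    time_point: int
    compartment: Compartment
    records: list[CloneRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[CloneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    @property
    def productive_records(self) -> list[CloneRecord]:
        return [r for r in self.records if r.productive]

    @property
    def productive_fraction(self) -> float:
        return float(sum(r.frequency for r in self.productive_records))

    def validate(self) -> None:
        """Check sample invariants: frequency closure and unique clone keys."""
        if self.records:
            total = sum(r.frequency for r in self.records)
            if abs(total - 1.0) > FREQUENCY_SUM_TOL:
                raise ValueError(
                    f"record frequencies sum to {total!r}, expected 1 +/- {FREQUENCY_SUM_TOL}"
                )
        keys = [r.clone_key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (aa, v, j, nt) clone keys in sample")

    @property
    def label(self) -> str:
        return f"{self.individual_id}/t{self.time_point}/{self.compartment.value}"


@dataclass(slots=True)
class TimeSeriesRepertoire:
    """All samples for one individual: ordered PBMC series plus optional
    flow-sorted memory / naive libraries."""

    individual_id: str
    pbmc_samples: list[RepertoireSample]
    memory_samples: list[RepertoireSample] = field(default_factory=list)
    naive_samples: list[RepertoireSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pbmc_samples = sorted(self.pbmc_samples, key=lambda s: s.time_point)
        self.memory_samples = sorted(self.memory_samples, key=lambda s: s.time_point)
        self.naive_samples = sorted(self.naive_samples, key=lambda s: s.time_point)
        for s in self.pbmc_samples + self.memory_samples + self.naive_samples:
            if s.individual_id != self.individual_id:
                raise ValueError(
                    f"sample {s.label} does not belong to individual {self.individual_id}"
                )

    @property
    def n_timepoints(self) -> int:
        return len(self.pbmc_samples)

    @property
    def all_samples(self) -> list[RepertoireSample]:
        return self.pbmc_samples + self.memory_samples + self.naive_samples
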