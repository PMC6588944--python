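"""Reading and writing immunoSEQ-style clonotype tables.

Input is a tab-delimited export with one row per clone and at least the
columns ``aminoAcid``, ``vGeneName``, ``jGeneName`` and a template-count
column (several dialects name it differently; see :data:`COUNT_COLUMN_ALIASES`).
A ``nucleotide`` column, when present, carries the CDR3 nucleotide sequence.
Gzip-compressed files are accepted transparently.

Relative abundances are always recomputed from counts over *all* rows —
productive and nonproductive — so a vendor ``frequencyCount (%)`` column is
only cross-checked, never trusted.
"""

from __future__ import annotations

import gzip
import logging
import math
from collections import OrderedDict
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .types import (
    CloneRecord,
    Compartment,
    RepertoireSample,
    TcrBeta,
    is_productive,
)

logger = logging.getLogger(__name__)

#: Accepted names for the template-count column, tried in order.
COUNT_COLUMN_ALIASES: tuple[str, ...] = ("count (templates/reads)", "count", "templates")

FREQUENCY_COLUMN = "frequencyCount (%)"
MANDATORY_COLUMNS = ("aminoAcid", "vGeneName", "jGeneName")


class RepertoireFormatError(ValueError):
    """Malformed repertoire table (missing column, bad count, ...)."""


def _find_count_column(columns: Sequence[str], aliases: Sequence[str]) -> str:
    for alias in aliases:
        if alias in columns:
            return alias
    raise RepertoireFormatError(
        f"no count column found; expected one of {list(aliases)}, got {list(columns)}"
    )


def read_repertoire_tsv(
    path,
    individual_id: str,
    time_point: int,
    compartment: Compartment | str,
    count_aliases: Sequence[str] = COUNT_COLUMN_ALIASES,
) -> RepertoireSample:
    """Read one clonotype TSV into a :class:`RepertoireSample`.

    Rows with a stop codon in the CDR3 or an unresolved V/J gene are retained
    and flagged nonproductive.  Duplicate (aminoAcid, V, J, nucleotide) rows
    are collapsed by summing counts.  Frequencies are recomputed from counts
    over all rows.

    Raises
    ------
    RepertoireFormatError
        If a mandatory column is missing (named in the message) or a count is
        negative / non-integer (reported with its 1-based file line number).
    """
    compartment = Compartment(compartment)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise RepertoireFormatError(f"missing mandatory column: {col!r}")
    count_col = _find_count_column(list(df.columns), count_aliases)
    has_nt = "nucleotide" in df.columns

    # collapse duplicate clone keys, preserving first-seen order
    collapsed: "OrderedDict[tuple, int]" = OrderedDict()
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        # positional zip: itertuples mangles column names containing spaces
        d = dict(zip(df.columns, row))
        count_str = str(d[count_col]).strip()
        try:
            count_f = float(count_str)
        except ValueError:
            raise RepertoireFormatError(
                f"line {i + 2}: count {count_str!r} is not a number"
            ) from None
        if count_f < 0 or not math.isclose(count_f, round(count_f), abs_tol=1e-9):
            raise RepertoireFormatError(
                f"line {i + 2}: count {count_str!r} is not a non-negative integer"
            )
        key = (
            str(d["aminoAcid"]).strip(),
            str(d["vGeneName"]).strip(),
            str(d["jGeneName"]).strip(),
            str(d["nucleotide"]).strip() if has_nt else "",
        )
        collapsed[key] = collapsed.get(key, 0) + int(round(count_f))

    total = sum(collapsed.values())
    records = []
    for (aa, v, j, nt), count in collapsed.items():
        records.append(
            CloneRecord(
                cdr3_aa=aa,
                v_gene=v,
                j_gene=j,
                cdr3_nt=nt,
                count=count,
                frequency=count / total if total else 0.0,
                productive=is_productive(aa, v, j),
            )
        )

    if FREQUENCY_COLUMN in df.columns and total:
        _check_vendor_frequencies(df, count_col, total, path)

    sample = RepertoireSample(individual_id, int(time_point), compartment, records)
    sample.validate()
    return sample


def _check_vendor_frequencies(df: pd.DataFrame, count_col: str, total: int, path) -> None:
    """Warn when a vendor frequency column disagrees with recomputed values."""
    try:
        vendor = pd.to_numeric(df[FREQUENCY_COLUMN], errors="coerce")
        counts = pd.to_numeric(df[count_col], errors="coerce")
    except Exception:  # pragma: no cover - defensive
        return
    recomputed = 100.0 * counts / total
    worst = (vendor - recomputed).abs().max()
    if worst > 0.1:
        logger.warning(
            "%s: vendor %r column deviates from recomputed frequencies by up to "
            "%.3f percentage points; recomputed values are used",
            path,
            FREQUENCY_COLUMN,
            worst,
        )


def write_repertoire_tsv(sample: RepertoireSample, path) -> None:
    """Write a sample back to the TSV dialect read by :func:`read_repertoire_tsv`.

    The round trip ``read(write(s))`` reproduces records, counts and
    frequencies (to 1e-9); output is byte-stable for ASCII gene labels.
    Paths ending in ``.gz`` are gzip-compressed.
    """
    lines = ["aminoAcid\tvGeneName\tjGeneName\tnucleotide\tcount (templates/reads)\tfrequencyCount (%)"]
    for r in sample.records:
        lines.append(
            f"{r.cdr3_aa}\t{r.v_gene}\t{r.j_gene}\t{r.cdr3_nt}\t{r.count}\t"
            f"{100.0 * r.frequency:.9g}"
        )
    data = ("\n".join(lines) + "\n").encode("utf-8")
    path = str(path)
    if path.endswith(".gz"):
        # fixed mtime so identical samples give byte-identical archives
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(data)
    else:
        with open(path, "wb") as fh:
            fh.write(data)


def productive_view(sample: RepertoireSample) -> RepertoireSample:
    """Restrict to productive records, leaving their frequencies untouched.

    The denominator of every frequency still includes nonproductive counts, so
    frequencies of the view sum to the sample's productive fraction (<= 1).
    """
    return RepertoireSample(
        individual_id=sample.individual_id,
        time_point=sample.time_point,
        compartment=sample.compartment,
        records=sample.productive_records,
    )


class TcrAggregate(NamedTuple):
    """Receptor-level aggregate over its member clones."""

    abundance: float
    nt_redundancy: int


def collapse_to_tcrs(sample: RepertoireSample) -> "OrderedDict[TcrBeta, TcrAggregate]":
    """Aggregate productive clones to receptor (amino-acid) identity.

    ``abundance`` sums member clone frequencies; ``nt_redundancy`` counts the
    distinct CDR3 nucleotide sequences encoding the receptor.
    """
    abund: dict[TcrBeta, float] = {}
    nts: dict[TcrBeta, set[str]] = {}
    for r in sample.records:
        if not r.productive:
            continue
        tcr = r.tcr
        abund[tcr] = abund.get(tcr, 0.0) + r.frequency
        nts.setdefault(tcr, set()).add(r.cdr3_nt)
    return OrderedDict(
        (tcr, TcrAggregate(abund[tcr], len(nts[tcr]))) for tcr in abund
    )
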