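"""Codon counting and the three codon-usage metrics: RSCU, NRSCU and FB.

For amino acid *i* with a synonymous family of size *n_i*, and ``x_ij`` the
count of its *j*-th codon over a gene set:

* ``RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij)`` — observed over expected under
  equal synonymous usage; ranges from 0 to *n_i*.
* ``NRSCU_ij = x_ij / sum_j x_ij`` — the within-family relative frequency;
  ranges 0 to 1 and equals ``RSCU_ij / n_i``.
* ``FB_ij = x_ij / sum_i sum_j x_ij`` — the codon's frequency among all
  sense codons of the set; unlike NRSCU it also reflects amino-acid usage.

Stop codons are counted but excluded from all three metrics: the FB
denominator runs over the 20 amino acids, and RSCU/NRSCU families are
amino-acid families.  A family with zero total count yields undefined (0/0)
entries, reported as NaN internally and ``NA`` in written tables — zero
would falsely signal avoidance of a codon.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from functools import cached_property, lru_cache
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.Data import CodonTable as _bio_codon_table

from .errors import FormatError, UsageError
from .genome_io import PathLike
from .heg import HegSet

log = logging.getLogger(__name__)

_BASES = "TCAG"

#: Canonical codon order shared by every table and profile (classic
#: codon-table order: TTT, TTC, TTA, TTG, TCT, ...).
CODONS: Tuple[str, ...] = tuple(
    first + second + third
    for first in _BASES
    for second in _BASES
    for third in _BASES
)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon -> amino acid mapping plus synonymous families."""

    name: str
    code: Mapping[str, str]  # codon -> one-letter amino acid, "*" for stop

    def __post_init__(self) -> None:
        if set(self.code) != set(CODONS):
            raise ValueError("genetic code must cover exactly the 64 codons")

    @cached_property
    def stop_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in CODONS if self.code[c] == "*")

    @cached_property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in CODONS if self.code[c] != "*")

    @cached_property
    def families(self) -> Dict[str, Tuple[str, ...]]:
        """Synonymous codon family for each amino acid, in canonical order."""
        fams: Dict[str, List[str]] = {}
        for codon in CODONS:
            residue = self.code[codon]
            if residue != "*":
                fams.setdefault(residue, []).append(codon)
        return {aa: tuple(codons) for aa, codons in fams.items()}

    def family_of(self, codon: str) -> Tuple[str, ...]:
        return self.families[self.code[codon]]


@lru_cache(maxsize=None)
def bacterial_code() -> GeneticCode:
    """The bacterial/archaeal genetic code (NCBI translation table 11)."""
    table = _bio_codon_table.unambiguous_dna_by_id[11]
    code = {**table.forward_table, **{c: "*" for c in table.stop_codons}}
    return GeneticCode(name="bacterial (table 11)", code=code)


@dataclass(frozen=True)
class CodonCounts:
    """Occurrence counts ``x_ij`` over the 64 codons for a gene set.

    ``total_sense`` excludes stop codons; triplets containing non-ACGT
    characters are skipped during counting and tallied in
    ``skipped_ambiguous``.  Input triplets reconcile as
    ``total_sense + skipped_stop + skipped_ambiguous``.
    """

    counts: Mapping[str, int]
    total_sense: int
    skipped_ambiguous: int
    skipped_stop: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(CODONS):
            raise ValueError("counts must cover exactly the 64 codons")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("codon counts must be non-negative")


def count_codons(
    sequences: Iterable[str], code: Optional[GeneticCode] = None
) -> CodonCounts:
    """Tally frame-0, non-overlapping codons over a collection of sequences.

    Every sequence length must be divisible by 3 (guaranteed by the
    extraction step's truncation policy).
    """
    code = code if code is not None else bacterial_code()
    tally: Counter = Counter()
    n_sequences = 0
    for seq in sequences:
        n_sequences += 1
        upper = str(seq).upper()
        if len(upper) % 3:
            raise ValueError(
                f"count_codons: sequence length {len(upper)} not divisible by 3"
            )
        tally.update(upper[i : i + 3] for i in range(0, len(upper), 3))
    if n_sequences == 0 or not tally:
        log.warning("count_codons: empty input, all counts zero")
    counts = {codon: tally.get(codon, 0) for codon in CODONS}
    skipped_ambiguous = sum(
        count for triplet, count in tally.items() if triplet not in code.code
    )
    if skipped_ambiguous:
        log.info(
            "count_codons: skipped %d triplets containing non-ACGT characters",
            skipped_ambiguous,
        )
    skipped_stop = sum(counts[c] for c in code.stop_codons)
    total_sense = sum(counts[c] for c in code.sense_codons)
    return CodonCounts(
        counts=counts,
        total_sense=total_sense,
        skipped_ambiguous=skipped_ambiguous,
        skipped_stop=skipped_stop,
    )


def rscu(
    counts: CodonCounts, code: Optional[GeneticCode] = None
) -> Dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    Families with zero total count yield NaN (undefined, not avoidance).
    """
    code = code if code is not None else bacterial_code()
    values: Dict[str, float] = {}
    for family in code.families.values():
        family_total = sum(counts.counts[c] for c in family)
        if family_total == 0:
            for codon in family:
                values[codon] = math.nan
        else:
            expected = family_total / len(family)
            for codon in family:
                values[codon] = counts.counts[codon] / expected
    return values


def nrscu(
    counts: CodonCounts, code: Optional[GeneticCode] = None
) -> Dict[str, float]:
    """Normalized RSCU: within-family relative frequency, in [0, 1]."""
    code = code if code is not None else bacterial_code()
    values: Dict[str, float] = {}
    for family in code.families.values():
        family_total = sum(counts.counts[c] for c in family)
        for codon in family:
            values[codon] = (
                counts.counts[codon] / family_total if family_total else math.nan
            )
    return values


def heg_fb(
    counts: CodonCounts, code: Optional[GeneticCode] = None
) -> Dict[str, float]:
    """Frequency bias: each codon's share of all sense codons in the set."""
    code = code if code is not None else bacterial_code()
    if counts.total_sense == 0:
        raise UsageError("heg_fb: no sense codons counted (total_sense == 0)")
    return {c: counts.counts[c] / counts.total_sense for c in code.sense_codons}


METRIC_COLUMNS = ("RSCU", "NRSCU", "HEG_FB")

_METRIC_ALIASES = {
    "rscu": "RSCU",
    "nrscu": "NRSCU",
    "fb": "HEG_FB",
    "heg_fb": "HEG_FB",
}


def metric_column(name: str) -> str:
    """Resolve a user-facing metric name (rscu/nrscu/fb) to its column."""
    try:
        return _METRIC_ALIASES[name.strip().lower()]
    except KeyError as exc:
        raise UsageError(
            f"unknown metric {name!r}; expected one of rscu, nrscu, fb"
        ) from exc


@dataclass
class MetricTable:
    """Per-codon metric values for one strain.

    ``data`` is a 64-row DataFrame indexed by codon in canonical order with
    columns ``AA``, ``Count``, ``RSCU``, ``NRSCU``, ``HEG_FB``.  Stop rows
    carry counts but no metric values; undefined family entries are NaN.
    """

    strain_label: str
    data: pd.DataFrame

    @property
    def undefined_codons(self) -> List[str]:
        """Sense codons whose family had zero total count."""
        sense = self.data["AA"] != "*"
        return list(self.data.index[sense & self.data["RSCU"].isna()])


def metric_table_from_counts(
    counts: CodonCounts,
    strain_label: str,
    code: Optional[GeneticCode] = None,
) -> MetricTable:
    """Assemble the full 64-row metric table from codon counts."""
    code = code if code is not None else bacterial_code()
    rscu_values = rscu(counts, code)
    nrscu_values = nrscu(counts, code)
    fb_values = (
        heg_fb(counts, code)
        if counts.total_sense > 0
        else {c: math.nan for c in code.sense_codons}
    )
    data = pd.DataFrame(
        {
            "AA": [code.code[c] for c in CODONS],
            "Count": [counts.counts[c] for c in CODONS],
            "RSCU": [rscu_values.get(c, math.nan) for c in CODONS],
            "NRSCU": [nrscu_values.get(c, math.nan) for c in CODONS],
            "HEG_FB": [fb_values.get(c, math.nan) for c in CODONS],
        },
        index=pd.Index(CODONS, name="Codon"),
    )
    return MetricTable(strain_label=strain_label, data=data)


def compute_metric_table(
    heg: HegSet, code: Optional[GeneticCode] = None
) -> MetricTable:
    """Count codons over a strain's HEG sequences and compute all metrics."""
    if not heg.members:
        raise UsageError("compute_metric_table: HEG set has no members")
    counts = count_codons((m.nt_sequence for m in heg.members), code)
    return metric_table_from_counts(counts, heg.strain_label, code)


def _format_value(value: float) -> str:
    return "NA" if pd.isna(value) else f"{value:.4f}"


def write_metric_table(table: MetricTable, path: PathLike) -> None:
    """Write one strain's table as tab-separated text, 4 decimal places.

    Columns: Codon, AA, Count, RSCU, NRSCU, HEG_FB.  The strain label is
    recorded in a leading ``# strain:`` comment so tables round-trip.
    """
    out = table.data.reset_index()
    for column in METRIC_COLUMNS:
        out[column] = out[column].map(_format_value)
    with Path(path).open("w") as handle:
        handle.write(f"# strain: {table.strain_label}\n")
        out.to_csv(handle, sep="\t", index=False)


def read_metric_table(path: PathLike) -> MetricTable:
    """Read a table written by :func:`write_metric_table`."""
    path = Path(path)
    strain_label = path.stem
    with path.open() as handle:
        first = handle.readline()
        if first.startswith("# strain:"):
            strain_label = first.partition(":")[2].strip()
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"Codon": str, "AA": str},
    )
    expected = ["Codon", "AA", "Count", *METRIC_COLUMNS]
    if list(frame.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, got {list(frame.columns)}"
        )
    frame = frame.set_index("Codon")
    missing = set(CODONS) - set(frame.index)
    if missing:
        raise FormatError(f"{path}: table missing codons {sorted(missing)}")
    frame = frame.loc[list(CODONS)]
    frame["Count"] = frame["Count"].astype(int)
    return MetricTable(strain_label=strain_label, data=frame)


def write_combined_table(
    tables: Sequence[MetricTable], path: PathLike
) -> None:
    """Write one row per codon with a column block per strain.

    Columns: Codon, AA, then ``<strain>|Count``, ``<strain>|RSCU``,
    ``<strain>|NRSCU``, ``<strain>|HEG_FB`` for each strain.
    """
    tables = list(tables)
    if not tables:
        raise UsageError("write_combined_table: no tables")
    labels = [t.strain_label for t in tables]
    if len(set(labels)) != len(labels):
        raise UsageError(f"write_combined_table: duplicate strain labels {labels}")
    wide = pd.DataFrame(
        {"Codon": list(CODONS), "AA": tables[0].data["AA"].to_numpy()}
    )
    for table in tables:
        wide[f"{table.strain_label}|Count"] = table.data["Count"].to_numpy()
        for column in METRIC_COLUMNS:
            wide[f"{table.strain_label}|{column}"] = [
                _format_value(v) for v in table.data[column]
            ]
    wide.to_csv(path, sep="\t", index=False)
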