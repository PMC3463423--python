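"""FASTA and NCBI PTT input/output plus elementary nucleotide-sequence operations.

Bacterial genomes arrive as a replicon nucleotide FASTA (``*.fna``) paired
with the NCBI protein-coding gene table (``*.ptt``).  PTT coordinates are
1-based and inclusive at both ends; every slice taken from a genome converts
from that convention explicitly.  Only the first FASTA record of an ``*.fna``
is treated as the replicon a PTT table refers to — multi-replicon organisms
are handled as independent fna/ptt pairs whose outputs the user may merge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio.Data import CodonTable as _bio_codon_table
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_letters

from .errors import ExtractionError, FormatError, UsageError

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Upper-case IUPAC nucleotide codes (ACGT plus ambiguity letters).
IUPAC_NUCLEOTIDES = frozenset(ambiguous_dna_letters.upper())

_COMPLEMENT_TABLE = str.maketrans(
    {base.upper(): comp.upper() for base, comp in ambiguous_dna_complement.items()}
)

_TABLE11 = _bio_codon_table.unambiguous_dna_by_id[11]

#: Bacterial genetic code (NCBI translation table 11): codon -> amino acid,
#: with stop codons mapped to "*".
CODE_TABLE_11 = {**_TABLE11.forward_table, **{c: "*" for c in _TABLE11.stop_codons}}


@dataclass(frozen=True)
class FastaRecord:
    """A minimally validated FASTA record (any alphabet, e.g. protein)."""

    identifier: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.identifier or re.search(r"\s", self.identifier):
            raise FormatError(
                f"FASTA identifier {self.identifier!r} is empty or contains whitespace"
            )
        if not self.sequence:
            raise FormatError(f"record {self.identifier!r} has an empty sequence")


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence with a validated IUPAC alphabet.

    The sequence is case-normalized to upper on construction (RefSeq files
    vary in case).  ``identifier`` is the FASTA header up to the first
    whitespace; ``description`` is the remainder.
    """

    identifier: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.identifier or re.search(r"\s", self.identifier):
            raise FormatError(
                f"sequence identifier {self.identifier!r} is empty or contains whitespace"
            )
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FormatError(f"record {self.identifier!r} has an empty sequence")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"record {self.identifier!r} contains non-IUPAC characters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PttRecord:
    """One protein-coding gene annotation from an NCBI PTT table.

    ``start``/``end`` are 1-based and both inclusive; ``strand`` is ``+`` or
    ``-``.  ``gene_name`` may be ``-`` when the annotation carries no symbol,
    in which case catalog matching falls back to the product text.  The
    ``code``/``cog`` columns are carried along unused so tables round-trip.
    """

    start: int
    end: int
    strand: str
    length_aa: int
    pid: str
    gene_name: str
    synonym_locus: str
    product: str
    code: str = "-"
    cog: str = "-"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"invalid coordinates {self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PttTable:
    """An ordered collection of :class:`PttRecord` as read from one file.

    File order is preserved and duplicate entries are permitted (real PTT
    files contain paralogs).
    """

    genome_label: str
    records: List[PttRecord]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> List[GenomeSequence]:
    """Read a nucleotide FASTA file into :class:`GenomeSequence` records.

    Multi-line sequences are concatenated and case-folded to upper.  Format
    violations (empty file, empty record, non-IUPAC character) raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    records: List[GenomeSequence] = []
    ident: str | None = None
    desc = ""
    chunks: List[str] = []
    header_line = 0

    def _finish() -> None:
        if ident is None:
            return
        if not chunks:
            raise FormatError(
                f"{path}: line {header_line}: record {ident!r} has no sequence"
            )
        records.append(GenomeSequence(ident, desc, "".join(chunks)))

    with path.open() as handle:
        saw_any = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if lineno == 1:
                if not line.startswith(">"):
                    raise FormatError(f"{path}: line 1: FASTA must begin with '>'")
            if not line:
                continue
            saw_any = True
            if line.startswith(">"):
                _finish()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                ident, _, desc = header.partition(" ")
                desc = desc.strip()
                chunks = []
                header_line = lineno
            else:
                bad = set(line.upper()) - IUPAC_NUCLEOTIDES
                if bad:
                    raise FormatError(
                        f"{path}: line {lineno}: non-IUPAC characters "
                        f"{''.join(sorted(bad))!r}"
                    )
                chunks.append(line.upper())
    if not saw_any:
        raise FormatError(f"{path}: empty FASTA file")
    _finish()
    return records


def write_fasta(
    records: Iterable[Union[GenomeSequence, FastaRecord]],
    path: PathLike,
    wrap: int = 70,
) -> None:
    """Write records as FASTA with sequence lines wrapped at ``wrap`` characters."""
    records = list(records)
    if not records:
        raise UsageError("write_fasta: no records to write")
    if wrap < 1:
        raise UsageError(f"write_fasta: wrap must be positive, got {wrap}")
    with Path(path).open("w") as handle:
        for rec in records:
            header = f">{rec.identifier} {rec.description}".rstrip()
            handle.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                handle.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# NCBI PTT

PTT_HEADER = (
    "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct"
)

_LOCATION_RE = re.compile(r"(\d+)\.\.(\d+)")


def read_ptt(path: PathLike) -> PttTable:
    """Read an NCBI PTT protein table.

    Expects the NCBI dialect: a free-text title line, an ``N proteins``
    line, the tab-separated column header, then tab-separated records whose
    Location field is ``start..end``.  Rows with an unparsable Location are
    rejected with their line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3 or not lines[2].lower().startswith("location"):
        raise FormatError(
            f"{path}: missing PTT header line "
            "(expected 'Location\\tStrand\\t...' on line 3)"
        )
    genome_label = lines[0].strip()
    records: List[PttRecord] = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise FormatError(
                f"{path}: line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        match = _LOCATION_RE.fullmatch(fields[0].strip())
        if not match:
            raise FormatError(
                f"{path}: line {lineno}: unparsable Location {fields[0]!r}"
            )
        start, end = int(match.group(1)), int(match.group(2))
        if start > end:
            raise FormatError(f"{path}: line {lineno}: start > end ({start}..{end})")
        strand = fields[1].strip()
        if strand not in ("+", "-"):
            raise FormatError(f"{path}: line {lineno}: bad strand {fields[1]!r}")
        try:
            length_aa = int(fields[2])
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: bad Length field {fields[2]!r}"
            ) from exc
        records.append(
            PttRecord(
                start=start,
                end=end,
                strand=strand,
                length_aa=length_aa,
                pid=fields[3].strip(),
                gene_name=fields[4].strip(),
                synonym_locus=fields[5].strip(),
                code=fields[6].strip(),
                cog=fields[7].strip(),
                product=fields[8].strip(),
            )
        )
    if not records:
        log.warning("%s: PTT table contains no data rows", path)
    return PttTable(genome_label=genome_label, records=records)


def write_ptt(table: PttTable, path: PathLike) -> None:
    """Write ``table`` in the same PTT dialect accepted by :func:`read_ptt`.

    The second line states the number of proteins, equal to the number of
    records.
    """
    if not table.records:
        raise UsageError("write_ptt: table has no records")
    lines = [table.genome_label, f"{len(table.records)} proteins", PTT_HEADER]
    for rec in table.records:
        lines.append(
            "\t".join(
                (
                    f"{rec.start}..{rec.end}",
                    rec.strand,
                    str(rec.length_aa),
                    rec.pid,
                    rec.gene_name,
                    rec.synonym_locus,
                    rec.code,
                    rec.cog,
                    rec.product,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence operations

def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (``N``→``N``, ``R``→``Y``, ...)."""
    upper = seq.upper()
    bad = set(upper) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(
            f"reverse_complement: non-IUPAC characters {''.join(sorted(bad))!r}"
        )
    return upper.translate(_COMPLEMENT_TABLE)[::-1]


def translate(seq: str) -> str:
    """Translate a frame-0 coding sequence under bacterial table 11.

    A terminal stop codon is dropped; internal stops are rendered ``*`` with
    a warning.  Codons containing any non-ACGT character translate to ``X``
    and are logged.  The length must already be divisible by 3 (upstream
    extraction truncates trailing partial codons).
    """
    upper = seq.upper()
    if len(upper) % 3:
        raise ValueError(
            f"translate: sequence length {len(upper)} is not divisible by 3"
        )
    n_codons = len(upper) // 3
    amino_acids: List[str] = []
    for k in range(n_codons):
        codon = upper[3 * k : 3 * k + 3]
        if set(codon) - set("ACGT"):
            log.warning("translate: ambiguous codon %s at position %d -> X", codon, k)
            amino_acids.append("X")
            continue
        residue = CODE_TABLE_11[codon]
        if residue == "*":
            if k == n_codons - 1:
                break  # terminal stop dropped
            log.warning("translate: internal stop codon %s at position %d", codon, k)
        amino_acids.append(residue)
    return "".join(amino_acids)


def extract_region(genome: GenomeSequence, start: int, end: int, strand: str) -> str:
    """Extract genome[start..end] (1-based, inclusive), minus-strand aware."""
    if not (1 <= start <= end <= len(genome)):
        raise ExtractionError(
            f"coordinates {start}..{end} outside genome "
            f"{genome.identifier!r} of length {len(genome)}"
        )
    sub = genome.sequence[start - 1 : end]
    if strand == "-":
        sub = reverse_complement(sub)
    return sub
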