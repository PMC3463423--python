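"""Identification and extraction of the canonical highly-expressed-gene set.

The reference set comprises 40 genes in which codon bias is strongest in
bacteria: the translation elongation factors Tu (*tufA*), Ts (*tsf*) and G
(*fusA*) plus 37 ribosomal-protein genes (*rplA*–*rplF*, *rplI*–*rplT*,
*rpsB*–*rpsT*).  Annotation tables name these genes inconsistently, so
matching proceeds in two steps: by gene symbol (canonical name or synonym,
case-insensitive), and — when the symbol column is absent or unrecognized —
by product-text patterns such as "50S ribosomal protein L1".  The synonym
table is user-extensible from a plain-text file, making a traditionally
by-hand curation step reproducible.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple, Union

from .errors import ExtractionError, FormatError, NoHegGenesError
from .genome_io import (
    FastaRecord,
    GenomeSequence,
    PathLike,
    PttRecord,
    PttTable,
    extract_region,
    translate,
    write_fasta,
    write_ptt,
)

log = logging.getLogger(__name__)

_RPL_LETTERS = "ABCDEF" + "IJKLMNOPQRST"  # L1-L6, L9-L20
_RPS_LETTERS = "BCDEFGHIJKLMNOPQRST"  # S2-S20

#: The 40 canonical gene symbols, in catalog order.
CANONICAL_HEG_GENES: Tuple[str, ...] = (
    ("tufA", "tsf", "fusA")
    + tuple(f"rpl{letter}" for letter in _RPL_LETTERS)
    + tuple(f"rps{letter}" for letter in _RPS_LETTERS)
)


def _ribosomal_protein_number(symbol: str) -> int:
    # rplA -> L1 ... rplT -> L20; rpsB -> S2 ... rpsT -> S20
    return ord(symbol[3]) - ord("A") + 1


def canonical_product(symbol: str) -> str:
    """The standard product annotation text for a canonical gene symbol."""
    if symbol == "tufA":
        return "translation elongation factor Tu"
    if symbol == "tsf":
        return "translation elongation factor Ts"
    if symbol == "fusA":
        return "translation elongation factor G"
    number = _ribosomal_protein_number(symbol)
    if symbol.startswith("rpl"):
        return f"50S ribosomal protein L{number}"
    return f"30S ribosomal protein S{number}"


@dataclass(frozen=True)
class HegCatalog:
    """The canonical 40-gene set with its synonym and product-pattern tables.

    ``synonyms`` maps lower-cased alternative gene symbols to canonical ones;
    ``product_patterns`` maps lower-cased substrings of product annotations to
    canonical symbols.  Product matching is case-insensitive substring search;
    when several patterns match, the longest wins (so "...protein S2" does not
    capture an "...protein S20" annotation).
    """

    canonical_names: Tuple[str, ...]
    synonyms: Mapping[str, str]
    product_patterns: Mapping[str, str]

    def __post_init__(self) -> None:
        known = set(self.canonical_names)
        for alias, target in {**self.synonyms, **self.product_patterns}.items():
            if target not in known:
                raise ValueError(
                    f"catalog maps {alias!r} to unknown symbol {target!r}"
                )

    @property
    def ribosomal_names(self) -> Tuple[str, ...]:
        return tuple(
            name
            for name in self.canonical_names
            if name.startswith(("rpl", "rps"))
        )

    def lookup_name(self, gene_name: str) -> Optional[str]:
        """Resolve a gene symbol (canonical or synonym) case-insensitively."""
        lowered = gene_name.strip().lower()
        for name in self.canonical_names:
            if lowered == name.lower():
                return name
        return self.synonyms.get(lowered)

    def match_product(self, product: str) -> Optional[str]:
        """Resolve a product annotation via substring patterns; longest wins."""
        lowered = product.lower()
        hits = [
            (len(pattern), pattern, symbol)
            for pattern, symbol in self.product_patterns.items()
            if pattern in lowered
        ]
        if not hits:
            return None
        hits.sort(key=lambda h: (-h[0], h[1]))
        if len({symbol for _, _, symbol in hits}) > 1:
            log.debug(
                "product %r matches several patterns; using longest (%r -> %s)",
                product,
                hits[0][1],
                hits[0][2],
            )
        return hits[0][2]

    def with_synonyms(self, extra: Mapping[str, str]) -> "HegCatalog":
        """Return a catalog extended with additional alias -> canonical pairs."""
        merged = dict(self.synonyms)
        for alias, target in extra.items():
            canonical = self.lookup_name(target) or target
            merged[alias.strip().lower()] = canonical
        return replace(self, synonyms=merged)


def default_catalog() -> HegCatalog:
    """Build the built-in 40-gene catalog with its synonym/pattern tables."""
    synonyms = {
        "tuf": "tufA",
        "tufb": "tufA",
        "tuf1": "tufA",
        "tuf2": "tufA",
        "fus": "fusA",
        "ts": "tsf",
    }
    patterns: Dict[str, str] = {
        "elongation factor tu": "tufA",
        "elongation factor ts": "tsf",
        "elongation factor g": "fusA",
        "ribosomal protein l7/l12": "rplL",
    }
    for symbol in CANONICAL_HEG_GENES[3:]:
        patterns[canonical_product(symbol).lower()] = symbol
    return HegCatalog(
        canonical_names=CANONICAL_HEG_GENES,
        synonyms=synonyms,
        product_patterns=patterns,
    )


def load_synonym_table(path: PathLike) -> Dict[str, str]:
    """Read a two-column tab-separated alias -> canonical synonym table.

    Blank lines and lines starting with ``#`` are ignored.
    """
    table: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}: line {lineno}: expected 'alias<TAB>canonical', got {line!r}"
            )
        table[fields[0].strip().lower()] = fields[1].strip()
    return table


class MatchResult(NamedTuple):
    """Outcome of catalog matching over one PTT table."""

    matches: List[Tuple[str, PttRecord]]
    missing: List[str]


def match_heg_genes(table: PttTable, catalog: HegCatalog) -> MatchResult:
    """Find all PTT records that belong to the highly-expressed-gene catalog.

    A record matches if (a) its gene symbol equals a canonical name or
    synonym, else (b) its product text matches a catalog product pattern.
    All matching copies are returned (paralogs included, with a warning);
    canonical symbols with no match are reported as missing.
    """
    matches: List[Tuple[str, PttRecord]] = []
    seen: Counter = Counter()
    for record in table.records:
        symbol = None
        if record.gene_name and record.gene_name != "-":
            symbol = catalog.lookup_name(record.gene_name)
        if symbol is None:
            symbol = catalog.match_product(record.product)
        if symbol is not None:
            matches.append((symbol, record))
            seen[symbol] += 1
    for symbol, copies in sorted(seen.items()):
        if copies > 1:
            log.warning("paralog: %s matched %d annotation records", symbol, copies)
    missing = [name for name in catalog.canonical_names if name not in seen]
    if not matches:
        log.warning("no highly-expressed genes matched in %r", table.genome_label)
    return MatchResult(matches=matches, missing=missing)


def extract_gene_sequence(genome: GenomeSequence, record: PttRecord) -> str:
    """Extract the coding sequence for one annotation record.

    The substring [start..end] (1-based, both inclusive) is taken from the
    genome and reverse-complemented for minus-strand genes.  If the resulting
    length is not a multiple of 3 the trailing 1-2 nt are dropped with a
    warning, so downstream codon counting stays in frame 0.
    """
    try:
        sub = extract_region(genome, record.start, record.end, record.strand)
    except ExtractionError as exc:
        raise ExtractionError(
            f"record {record.pid}/{record.gene_name}: {exc}"
        ) from exc
    remainder = len(sub) % 3
    if remainder:
        log.warning(
            "gene %s (%d..%d): length %d not divisible by 3; dropping %d trailing nt",
            record.gene_name,
            record.start,
            record.end,
            len(sub),
            remainder,
        )
        sub = sub[: len(sub) - remainder]
    return sub


@dataclass(frozen=True)
class HegMember:
    """One extracted gene: catalog symbol, annotation, and its sequences."""

    symbol: str
    record: PttRecord
    nt_sequence: str
    aa_sequence: str


@dataclass
class HegSet:
    """The highly-expressed-gene set extracted from one strain."""

    strain_label: str
    members: List[HegMember]
    missing: List[str]

    def __len__(self) -> int:
        return len(self.members)

    def to_ptt(self) -> PttTable:
        """The HEG-only annotation table, in extraction order."""
        return PttTable(
            genome_label=f"{self.strain_label} highly expressed genes",
            records=[member.record for member in self.members],
        )

    def _identifiers(self) -> List[str]:
        strain = self.strain_label.replace(" ", "_")
        totals = Counter(member.symbol for member in self.members)
        running: Counter = Counter()
        identifiers = []
        for member in self.members:
            running[member.symbol] += 1
            suffix = (
                f".{running[member.symbol]}" if totals[member.symbol] > 1 else ""
            )
            identifiers.append(f"{strain}|{member.symbol}{suffix}")
        return identifiers

    def nt_records(self) -> List[FastaRecord]:
        return [
            FastaRecord(ident, member.record.product, member.nt_sequence)
            for ident, member in zip(self._identifiers(), self.members)
        ]

    def aa_records(self) -> List[FastaRecord]:
        return [
            FastaRecord(ident, member.record.product, member.aa_sequence)
            for ident, member in zip(self._identifiers(), self.members)
        ]


def build_heg_set(
    genome: GenomeSequence,
    table: PttTable,
    catalog: Optional[HegCatalog] = None,
    *,
    first_copy_only: bool = False,
    strain_label: Optional[str] = None,
) -> HegSet:
    """Match, extract and translate the highly-expressed-gene set of a strain.

    Missing catalog genes do not abort the build (many genomes lack, e.g., an
    *rplI* annotation under that name); a completeness report is logged.  A
    table in which no catalog gene matches at all raises
    :class:`NoHegGenesError`.  With ``first_copy_only`` every catalog symbol
    keeps only its first annotated copy; by default all copies are kept and
    counted.
    """
    catalog = catalog if catalog is not None else default_catalog()
    result = match_heg_genes(table, catalog)
    if not result.matches:
        raise NoHegGenesError(
            f"no HEG genes found in annotation table {table.genome_label!r}"
        )
    matches = result.matches
    if first_copy_only:
        kept: List[Tuple[str, PttRecord]] = []
        used = set()
        for symbol, record in matches:
            if symbol in used:
                continue
            used.add(symbol)
            kept.append((symbol, record))
        if len(kept) < len(matches):
            log.info(
                "first-copy-only: dropped %d paralogous copies",
                len(matches) - len(kept),
            )
        matches = kept
    members = []
    for symbol, record in matches:
        nt = extract_gene_sequence(genome, record)
        members.append(HegMember(symbol, record, nt, translate(nt)))
    label = strain_label if strain_label is not None else genome.identifier
    log.info(
        "%s: %d/%d catalog genes found (%d records)%s",
        label,
        len(catalog.canonical_names) - len(result.missing),
        len(catalog.canonical_names),
        len(members),
        f"; missing: {', '.join(result.missing)}" if result.missing else "",
    )
    return HegSet(strain_label=label, members=members, missing=result.missing)


def write_heg_artifacts(heg: HegSet, outdir: PathLike) -> Dict[str, Path]:
    """Write the per-strain deliverables: HEG-only PTT and nt/aa FASTA files.

    Returns a mapping of artifact kind to the written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = heg.strain_label.replace(" ", "_")
    paths = {
        "ptt": outdir / f"{stem}_heg.ptt",
        "nt_fasta": outdir / f"{stem}_heg_nt.fasta",
        "aa_fasta": outdir / f"{stem}_heg_aa.fasta",
    }
    write_ptt(heg.to_ptt(), paths["ptt"])
    write_fasta(heg.nt_records(), paths["nt_fasta"])
    write_fasta(heg.aa_records(), paths["aa_fasta"])
    return paths
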