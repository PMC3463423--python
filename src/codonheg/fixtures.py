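"""Synthetic genomes with planted highly-expressed genes.

The generator emits an (fna, ptt)-style pair — a :class:`GenomeSequence`
plus a :class:`PttTable` — in which every catalog gene is planted with a
known, configurable per-family codon distribution.  Genes are drawn
codon-by-codon: an amino acid is sampled (uniform over the 20 by default),
then a codon within its synonymous family from the planted probabilities
``p_ij``.  A start codon ATG is forced and one stop codon appended; genes
alternate strands and minus-strand genes are stored reverse-complemented in
the genome with coordinates and strand recorded in the annotation table.
Everything is driven by a single pseudo-random stream seeded from
``FixtureSpec.seed``, so a given spec is byte-reproducible.

The default codon distribution is strongly biased — half the probability
mass on one codon per family — emulating the pronounced bias of highly
expressed genes in fast-growing bacteria.  Real genomes additionally have
non-uniform amino-acid composition, annotation errors and intergenic
structure that the fixtures do not model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import UsageError
from .genome_io import GenomeSequence, PathLike, PttRecord, PttTable, reverse_complement, write_fasta, write_ptt
from .heg import CANONICAL_HEG_GENES, build_heg_set, canonical_product, default_catalog
from .metrics import GeneticCode, MetricTable, bacterial_code, compute_metric_table

log = logging.getLogger(__name__)

CodonProbs = Mapping[str, Mapping[str, float]]


def uniform_codon_probs(code: Optional[GeneticCode] = None) -> Dict[str, Dict[str, float]]:
    """Equal usage within every synonymous family."""
    code = code if code is not None else bacterial_code()
    return {
        aa: {codon: 1.0 / len(family) for codon in family}
        for aa, family in code.families.items()
    }


def biased_codon_probs(
    favored: str = "first",
    weight: float = 0.5,
    code: Optional[GeneticCode] = None,
) -> Dict[str, Dict[str, float]]:
    """Per-family distributions with ``weight`` on one favored codon.

    ``favored`` selects the first or last codon of each family (canonical
    order); the remaining mass is spread evenly over the other codons.
    Using "first" vs "last" yields two well-separated usage regimes for
    group-separation experiments.
    """
    if favored not in ("first", "last"):
        raise UsageError(f"favored must be 'first' or 'last', got {favored!r}")
    if not 0.0 < weight <= 1.0:
        raise UsageError(f"weight must be in (0, 1], got {weight}")
    code = code if code is not None else bacterial_code()
    probs: Dict[str, Dict[str, float]] = {}
    for aa, family in code.families.items():
        if len(family) == 1:
            probs[aa] = {family[0]: 1.0}
            continue
        rest = (1.0 - weight) / (len(family) - 1)
        vector = {codon: rest for codon in family}
        vector[family[0] if favored == "first" else family[-1]] = weight
        probs[aa] = vector
    return probs


@dataclass
class FixtureSpec:
    """Parameters of one synthetic genome.

    ``gene_length`` is the number of body codons drawn from the planted
    distributions per gene; the forced ATG start and the appended stop are
    extra, so each gene spans ``3 * (gene_length + 2)`` nt.  ``strands``
    defaults to alternating +/-; ``gene_name_aliases`` lets individual genes
    be written under a synonym (or ``-``) to exercise catalog matching.
    """

    seed: int = 0
    codon_probs: Optional[CodonProbs] = None  # default: biased_codon_probs()
    genes: Tuple[str, ...] = CANONICAL_HEG_GENES
    gene_length: int = 100
    filler: int = 50
    aa_freqs: Optional[Mapping[str, float]] = None  # default: uniform over 20
    strands: Optional[Sequence[str]] = None
    gene_name_aliases: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: PathLike) -> "FixtureSpec":
        """Load a spec from YAML or ``key=value`` lines.

        Recognized keys: seed, gene_length, filler, genes, favored
        ("first"/"last"), bias_weight.
        """
        text = Path(path).read_text()
        stripped = text.strip()
        first_line = stripped.splitlines()[0] if stripped else ""
        if "=" in first_line and ":" not in first_line:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = yaml.safe_load(value.strip())
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise UsageError(f"{path}: fixture spec must be a mapping")
        known = {"seed", "gene_length", "filler", "genes", "favored", "bias_weight"}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"{path}: unknown fixture keys {sorted(unknown)}")
        kwargs: Dict[str, object] = {}
        for key in ("seed", "gene_length", "filler"):
            if key in data:
                kwargs[key] = int(data[key])
        if "genes" in data:
            kwargs["genes"] = tuple(data["genes"])
        if "favored" in data or "bias_weight" in data:
            kwargs["codon_probs"] = biased_codon_probs(
                favored=data.get("favored", "first"),
                weight=float(data.get("bias_weight", 0.5)),
            )
        return cls(**kwargs)  # type: ignore[arg-type]


def _validate_probs(probs: CodonProbs, code: GeneticCode) -> None:
    for aa, family in code.families.items():
        if aa not in probs:
            raise UsageError(f"codon_probs missing amino acid {aa!r}")
        vector = probs[aa]
        if set(vector) != set(family):
            raise UsageError(
                f"codon_probs[{aa!r}] keys {sorted(vector)} != family {sorted(family)}"
            )
        total = float(sum(vector.values()))
        if abs(total - 1.0) > 1e-9:
            raise UsageError(
                f"codon_probs[{aa!r}] sums to {total}, not 1 (tolerance 1e-9)"
            )
        if any(p < 0 for p in vector.values()):
            raise UsageError(f"codon_probs[{aa!r}] contains negative probabilities")


def _draw_codons(
    rng: np.random.Generator,
    n_codons: int,
    amino_acids: Sequence[str],
    aa_p: np.ndarray,
    probs: CodonProbs,
    code: GeneticCode,
) -> str:
    aa_index = rng.choice(len(amino_acids), size=n_codons, p=aa_p)
    out = np.empty(n_codons, dtype=object)
    for i, aa in enumerate(amino_acids):
        mask = aa_index == i
        count = int(mask.sum())
        if not count:
            continue
        family = code.families[aa]
        weights = np.array([probs[aa][codon] for codon in family], dtype=float)
        weights = weights / weights.sum()
        out[mask] = rng.choice(np.array(family, dtype=object), size=count, p=weights)
    return "".join(out.tolist())


def generate_fixture(
    spec: FixtureSpec, code: Optional[GeneticCode] = None
) -> Tuple[GenomeSequence, PttTable]:
    """Build a synthetic genome and its annotation table from a spec."""
    code = code if code is not None else bacterial_code()
    probs = spec.codon_probs if spec.codon_probs is not None else biased_codon_probs()
    _validate_probs(probs, code)
    amino_acids = sorted(code.families)
    if spec.aa_freqs is None:
        aa_p = np.full(len(amino_acids), 1.0 / len(amino_acids))
    else:
        aa_p = np.array([spec.aa_freqs.get(aa, 0.0) for aa in amino_acids], float)
        if abs(aa_p.sum() - 1.0) > 1e-9:
            raise UsageError(f"aa_freqs sums to {aa_p.sum()}, not 1")
    strands = (
        tuple(spec.strands)
        if spec.strands is not None
        else tuple("+-"[i % 2] for i in range(len(spec.genes)))
    )
    if len(strands) != len(spec.genes):
        raise UsageError("strands must match genes in length")
    if spec.gene_length < 1 or spec.filler < 0:
        raise UsageError("gene_length must be >= 1 and filler >= 0")

    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"), dtype=object)
    parts = []
    records = []
    position = 0
    for index, (symbol, strand) in enumerate(zip(spec.genes, strands)):
        filler = "".join(rng.choice(bases, size=spec.filler).tolist())
        body = _draw_codons(rng, spec.gene_length, amino_acids, aa_p, probs, code)
        stop = code.stop_codons[int(rng.integers(len(code.stop_codons)))]
        gene = "ATG" + body + stop
        placed = gene if strand == "+" else reverse_complement(gene)
        parts.extend((filler, placed))
        start = position + spec.filler + 1
        end = start + len(gene) - 1
        position = end
        records.append(
            PttRecord(
                start=start,
                end=end,
                strand=strand,
                length_aa=len(gene) // 3 - 1,
                pid=str(index + 1),
                gene_name=spec.gene_name_aliases.get(symbol, symbol),
                synonym_locus=f"SYN{index + 1:04d}",
                product=canonical_product(symbol)
                if symbol in CANONICAL_HEG_GENES
                else symbol,
            )
        )
    parts.append("".join(rng.choice(bases, size=spec.filler).tolist()))
    sequence = "".join(parts)
    genome = GenomeSequence(
        identifier=f"fixture_seed{spec.seed}",
        description="synthetic genome with planted highly expressed genes",
        sequence=sequence,
    )
    table = PttTable(
        genome_label=(
            f"synthetic fixture genome (seed {spec.seed}) - 1..{len(sequence)}"
        ),
        records=records,
    )
    log.info(
        "fixture seed %d: %d genes, genome length %d nt",
        spec.seed,
        len(records),
        len(sequence),
    )
    return genome, table


def write_fixture(
    spec: FixtureSpec, outdir: PathLike, basename: str = "fixture"
) -> Dict[str, Path]:
    """Write the fixture genome and annotation as ``.fna`` and ``.ptt``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, table = generate_fixture(spec)
    paths = {"fna": outdir / f"{basename}.fna", "ptt": outdir / f"{basename}.ptt"}
    write_fasta([genome], paths["fna"])
    write_ptt(table, paths["ptt"])
    return paths


def metric_table_for(
    spec: FixtureSpec, strain_label: Optional[str] = None
) -> MetricTable:
    """Convenience: generate a fixture strain and compute its metric table."""
    genome, table = generate_fixture(spec)
    heg = build_heg_set(
        genome, table, default_catalog(), strain_label=strain_label
    )
    result = compute_metric_table(heg)
    return result
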