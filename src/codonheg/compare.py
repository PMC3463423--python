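"""Inter-strain comparison of codon-usage profiles.

Each strain is reduced to a profile vector of one metric (NRSCU by default)
over the 59 informative sense codons — the 61 sense codons minus the two
single-codon families ATG (Met) and TGG (Trp), which are identically 1
under RSCU/NRSCU and would inflate correlations.  Pairwise Pearson
correlation r is mapped to a distance ``(1 - r)/2``, so a perfectly
correlated pair is at distance 0 and a perfectly anticorrelated pair at
distance 1.  The resulting matrix feeds least-squares tree fitting
(:mod:`codonheg.treefit`) and can be written in PHYLIP square format.

Per-codon one-way ANOVA across species groups quantifies whether usage of
individual codons differs between groups; raw p-values are reported next to
Benjamini–Hochberg adjusted ones across the tested codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ProfileError, UsageError
from .genome_io import PathLike
from .metrics import (
    CODONS,
    GeneticCode,
    MetricTable,
    bacterial_code,
    metric_column,
)

log = logging.getLogger(__name__)


def informative_codons(
    code: Optional[GeneticCode] = None,
    *,
    include_single_codon_families: bool = False,
) -> Tuple[str, ...]:
    """Sense codons used in profiles, in canonical order.

    Single-codon families (ATG, TGG under table 11) are excluded by default;
    they carry no synonymous-usage information.
    """
    code = code if code is not None else bacterial_code()
    return tuple(
        codon
        for codon in code.sense_codons
        if include_single_codon_families or len(code.family_of(codon)) > 1
    )


@dataclass(frozen=True)
class StrainProfile:
    """One strain's metric values over the shared informative-codon order.

    Undefined entries (families absent from the strain's gene set) are NaN
    and masked out pairwise during correlation.
    """

    strain_label: str
    metric: str
    codons: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.codons) != len(self.values):
            raise ValueError("profile codons and values differ in length")


def make_profile(
    table: MetricTable,
    metric: str = "nrscu",
    *,
    include_single_codon_families: bool = False,
    code: Optional[GeneticCode] = None,
) -> StrainProfile:
    """Extract one strain's profile vector from its metric table."""
    column = metric_column(metric)
    codons = informative_codons(
        code, include_single_codon_families=include_single_codon_families
    )
    values = table.data.loc[list(codons), column].to_numpy(dtype=float)
    return StrainProfile(
        strain_label=table.strain_label,
        metric=column,
        codons=codons,
        values=values,
    )


def profile_correlation(
    a: StrainProfile, b: StrainProfile, method: str = "pearson"
) -> float:
    """Correlation between two profiles over their jointly defined entries.

    Requires the same metric and codon ordering, at least 3 jointly defined
    entries, and non-zero variance in both vectors.
    """
    if a.metric != b.metric or a.codons != b.codons:
        raise ProfileError(
            f"{a.strain_label} vs {b.strain_label}: profiles are not comparable "
            f"(metric/codon ordering differs)"
        )
    joint = np.isfinite(a.values) & np.isfinite(b.values)
    n_joint = int(joint.sum())
    if n_joint < 3:
        raise ProfileError(
            f"{a.strain_label} vs {b.strain_label}: only {n_joint} jointly "
            "defined codons (need >= 3)"
        )
    x, y = a.values[joint], b.values[joint]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ProfileError(
            f"{a.strain_label} vs {b.strain_label}: zero variance in a profile"
        )
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise UsageError(f"unknown correlation method {method!r}")
    return float(r)


def correlation_distance(r: float) -> float:
    """Map a correlation coefficient to a distance: ``(1 - r)/2``.

    r = +1 gives 0, r = -1 gives 1.  Values outside [-1, 1] by more than
    1e-9 are rejected; round-off just beyond the bounds is clipped.
    """
    if r < -1 - 1e-9 or r > 1 + 1e-9:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return (1.0 - min(1.0, max(-1.0, r))) / 2.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise (1-r)/2 distances among strain profiles."""

    labels: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        finite = self.d[np.isfinite(self.d)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-9):
            raise ValueError("distances must lie in [0, 1]")


def build_distance_matrix(
    profiles: Sequence[StrainProfile], method: str = "pearson"
) -> DistanceMatrix:
    """All-pairs correlation distances among strain profiles."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise UsageError("build_distance_matrix: need at least 2 profiles")
    labels = tuple(p.strain_label for p in profiles)
    if len(set(labels)) != len(labels):
        raise UsageError(f"duplicate strain labels: {labels}")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = profile_correlation(profiles[i], profiles[j], method=method)
            d[i, j] = d[j, i] = correlation_distance(r)
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# PHYLIP square distance format

def _phylip_names(labels: Sequence[str]) -> List[str]:
    names: List[str] = []
    used = set()
    for label in labels:
        base = label.replace(" ", "_")[:10]
        name, k = base, 1
        while name in used:
            suffix = str(k)
            name = base[: 10 - len(suffix)] + suffix
            k += 1
        if name != base[:10] or len(label.replace(" ", "_")) > 10:
            log.warning("PHYLIP name %r shortened/uniquified to %r", label, name)
        used.add(name)
        names.append(name)
    return names


def write_phylip_matrix(matrix: DistanceMatrix, path: PathLike) -> None:
    """Write the matrix in PHYLIP square format (10-character taxon names)."""
    names = _phylip_names(matrix.labels)
    with Path(path).open("w") as handle:
        handle.write(f"{len(names)}\n")
        for name, row in zip(names, matrix.d):
            handle.write(
                f"{name:<10}" + " ".join(f"{value:.6f}" for value in row) + "\n"
            )


def read_phylip_matrix(path: PathLike) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix written by this package."""
    lines = [line for line in Path(path).read_text().splitlines() if line.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        labels.append(line[:10].strip())
        rows.append([float(x) for x in line[10:].split()])
    return DistanceMatrix(labels=tuple(labels), d=np.asarray(rows))


# ---------------------------------------------------------------------------
# Per-codon ANOVA across species groups

def per_codon_anova(
    groups: Mapping[str, Sequence[MetricTable]],
    metric: str = "nrscu",
    *,
    code: Optional[GeneticCode] = None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """One-way fixed-effects ANOVA per codon on a metric across groups.

    Each group contributes one metric value per strain per codon.  Strains
    in which a codon is undefined are dropped for that codon; a codon with
    fewer than two usable groups (>= 2 strains each) is skipped.  Returns a
    per-codon table (F, raw p, Benjamini–Hochberg adjusted p across the
    tested codons) and a global summary.
    """
    if len(groups) < 2:
        raise UsageError("per_codon_anova: need at least 2 groups")
    for name, tables in groups.items():
        if len(tables) < 2:
            raise UsageError(
                f"per_codon_anova: group {name!r} has {len(tables)} strains (need >= 2)"
            )
    column = metric_column(metric)
    codons = informative_codons(code)
    records = []
    for codon in codons:
        samples = []
        for name, tables in groups.items():
            values = np.array(
                [float(t.data.at[codon, column]) for t in tables], dtype=float
            )
            usable = values[np.isfinite(values)]
            if usable.size < len(values):
                log.debug(
                    "codon %s: dropped %d undefined strains in group %r",
                    codon,
                    len(values) - usable.size,
                    name,
                )
            if usable.size >= 2:
                samples.append(usable)
        if len(samples) < 2:
            log.info("codon %s: fewer than 2 usable groups, skipped", codon)
            continue
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            # all observations identical: no variation to test
            f_stat, p_value = 0.0, 1.0
        else:
            f_stat, p_value = stats.f_oneway(*samples)
        records.append((codon, float(f_stat), float(p_value)))
    if not records:
        raise UsageError("per_codon_anova: no codon had 2 usable groups")
    result = pd.DataFrame(records, columns=["Codon", "F", "p"])
    result["p_adj"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    summary = {
        "metric": column,
        "n_codons_tested": int(len(result)),
        "n_raw_p_below_0.05": int((result["p"] < 0.05).sum()),
        "n_adj_p_below_0.05": int((result["p_adj"] < 0.05).sum()),
        "min_p_adj": float(result["p_adj"].min()),
    }
    return result, summary


def write_anova_table(table: pd.DataFrame, path: PathLike) -> None:
    """Write per-codon ANOVA results as tab-separated text."""
    out = table.copy()
    for column in ("F", "p", "p_adj"):
        out[column] = out[column].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
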