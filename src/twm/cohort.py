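"""Cohort-level recurrence and over-representation statistics.

A cohort is summarized as a binary gene-by-case mutation matrix.  Two
filters reproduce the descriptive statistics a small-cohort study reports:

* recurrence — genes mutated in strictly more than a fixed number of cases;
* over-representation — genes whose cohort incidence percent (rounded
  half-up, as displayed) strictly exceeds a fold multiple of a reference
  incidence percent (e.g. TCGA-SKCM).

No significance test is attached: with a handful of cases the comparison is
a descriptive fold filter, not an enrichment test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import VariantRecord

__all__ = [
    "CohortMatrix",
    "build_matrix",
    "incidence_percent",
    "recurrent_genes",
    "overrepresented_genes",
    "write_matrix",
    "read_reference_percents",
]

log = logging.getLogger(__name__)


@dataclass
class CohortMatrix:
    """Binary genes x cases mutation matrix with optional reference incidences."""

    genes: tuple[str, ...]
    cases: tuple[str, ...]
    mutated: np.ndarray
    tcga_percent: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.cases = tuple(self.cases)
        if not self.cases:
            raise ValueError("cohort has no cases")
        self.mutated = np.asarray(self.mutated, dtype=np.int8)
        if self.mutated.shape != (len(self.genes), len(self.cases)):
            raise ValueError(
                f"matrix shape {self.mutated.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cases)} cases"
            )
        if not np.isin(self.mutated, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    def n_cases_mutated(self, gene: str) -> int:
        return int(self.mutated[self.genes.index(gene)].sum())


def build_matrix(
    variants: Iterable[VariantRecord], cases: Sequence[str]
) -> CohortMatrix:
    """Gene-by-case presence matrix: 1 iff the gene is hit in the case.

    Variant multiplicity within a gene/case is collapsed (idempotent).
    Variants without a gene symbol are ignored; a variant from a case not
    listed in *cases* is an error.
    """
    cases = tuple(cases)
    case_index = {c: j for j, c in enumerate(cases)}
    genes: list[str] = []
    gene_index: dict[str, int] = {}
    hits: list[tuple[int, int]] = []
    for v in variants:
        if not v.gene:
            continue
        if v.case_id not in case_index:
            raise ValueError(f"variant case {v.case_id!r} not in cohort case list")
        if v.gene not in gene_index:
            gene_index[v.gene] = len(genes)
            genes.append(v.gene)
        hits.append((gene_index[v.gene], case_index[v.case_id]))
    mat = np.zeros((len(genes), len(cases)), dtype=np.int8)
    for g, c in hits:
        mat[g, c] = 1
    return CohortMatrix(genes=tuple(genes), cases=cases, mutated=mat)


def incidence_percent(n_mutated: int, n_cases: int) -> int:
    """Cohort incidence as an integer percent, rounded half-up.

    Half-up (not banker's) rounding matches how small-cohort incidences are
    conventionally displayed: 6/7 -> 86, 4/7 -> 57, 3/7 -> 43.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0 <= n_mutated <= n_cases:
        raise ValueError(f"n_mutated {n_mutated} outside [0, {n_cases}]")
    return int(np.floor(100.0 * n_mutated / n_cases + 0.5))


def recurrent_genes(matrix: CohortMatrix, min_cases_exclusive: int = 2) -> list[str]:
    """Genes mutated in strictly more than *min_cases_exclusive* cases.

    Returned in the matrix's gene order.
    """
    counts = matrix.mutated.sum(axis=1)
    return [g for g, n in zip(matrix.genes, counts) if n > min_cases_exclusive]


def overrepresented_genes(matrix: CohortMatrix, fold: float = 2.0) -> list[str]:
    """Genes whose displayed incidence percent exceeds *fold* x reference percent.

    The comparison uses the rounded cohort percent (as displayed) against
    the reference percent, strict inequality.  Genes without a reference
    percent are skipped with a warning.
    """
    out = []
    n_cases = len(matrix.cases)
    counts = matrix.mutated.sum(axis=1)
    for gene, n in zip(matrix.genes, counts):
        if gene not in matrix.tcga_percent:
            log.warning("no reference percent for %s; skipped", gene)
            continue
        if incidence_percent(int(n), n_cases) > fold * matrix.tcga_percent[gene]:
            out.append(gene)
    return out


def write_matrix(matrix: CohortMatrix, path: str | Path) -> None:
    """Genes x cases 0/1 TSV with a leading ``gene`` column."""
    df = pd.DataFrame(matrix.mutated, index=list(matrix.genes), columns=list(matrix.cases))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_reference_percents(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene, percent) of reference incidences."""
    df = pd.read_csv(path, sep="\t")
    gene_col, pct_col = df.columns[0], df.columns[1]
    return {str(g): float(p) for g, p in zip(df[gene_col], df[pct_col])}
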