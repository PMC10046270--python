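"""Bundled reference tables for a seven-case triple-wild-type melanoma cohort.

Raw sequencing data for triple-wild-type (BRAF/RAS/KIT wild-type) cutaneous
melanoma cohorts is rarely public; what circulates are the published
per-case summary numbers.  This module ships those summaries as structured
inputs so the cohort-level statistics can be exercised end to end:

* per-case genome-wide mutation totals, pathogenic-per-exome counts and the
  whole-genome TMB values derived from them;
* the top-mutated-gene table — each gene's number of mutated cases out of
  seven and its TCGA-SKCM reference incidence percent.

``top_gene_matrix`` expands the gene table into a binary gene-by-case
matrix realizing the published per-case counts (plus optional decoy genes
below the recurrence threshold), the fixture on which the recurrence and
over-representation filters are validated.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortMatrix

__all__ = [
    "COHORT_CASES",
    "CASE_TOTAL_MUTATIONS",
    "CASE_PATHOGENIC_PER_EXOME",
    "CASE_WGS_TMB_PER_MB",
    "TOP_GENES",
    "top_gene_matrix",
]

COHORT_CASES: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7")

#: Genome-wide somatic mutation totals per case.
CASE_TOTAL_MUTATIONS: dict[str, int] = {
    "1": 85_846, "2": 2_576, "3": 28_148, "4": 41_635,
    "5": 35_410, "6": 293_162, "7": 539_258,
}

#: Pathogenic mutations per exome, as annotated upstream.
CASE_PATHOGENIC_PER_EXOME: dict[str, int] = {
    "1": 53, "2": 4, "3": 27, "4": 24, "5": 27, "6": 189, "7": 315,
}

#: Whole-genome TMB (mutations/Mb) as published per case.  The per-case
#: callable genome sizes behind these values were not published; at the
#: 3300 Mb default divisor the totals above reproduce them only to ~3%.
CASE_WGS_TMB_PER_MB: dict[str, float] = {
    "1": 25.8, "2": 0.8, "3": 8.5, "4": 12.4, "5": 10.6, "6": 88.8, "7": 163.3,
}

#: Top mutated genes: (symbol, cases mutated out of 7, TCGA-SKCM percent).
TOP_GENES: tuple[tuple[str, int, float], ...] = (
    ("ANK3", 4, 38.0),
    ("BMPER", 3, 12.0),
    ("BRINP2", 3, 13.0),
    ("C6", 3, 24.0),
    ("CTNND2", 3, 14.0),
    ("CSMD1", 3, 40.0),
    ("DNAH5", 3, 56.0),
    ("LAMB4", 3, 15.0),
    ("MUC4", 4, 18.0),
    ("MROH2B", 3, 7.0),
    ("MUC17", 3, 31.0),
    ("PCLO", 4, 49.0),
    ("POM121L12", 3, 13.0),
    ("RELN", 3, 27.0),
    ("TERT", 6, 77.0),
    ("TTN", 4, 80.0),
    ("UNC13C", 3, 30.0),
    ("ZFHX4", 4, 33.0),
    ("ZFPM2", 3, 18.0),
)


def top_gene_matrix(n_decoys: int = 10) -> CohortMatrix:
    """Binary gene-by-case matrix realizing the published per-gene case counts.

    Each top gene is marked mutated in its published number of cases
    (assigned to the first cases in order; which cases carry a hit does not
    affect recurrence or incidence, which depend only on the count).
    *n_decoys* extra genes mutated in 0, 1 or 2 cases (cycling) are
    appended; none can pass the strictly-more-than-two-cases recurrence
    filter, so they probe its boundary.
    """
    genes = [g for g, _, _ in TOP_GENES]
    rows = [[1] * n + [0] * (7 - n) for _, n, _ in TOP_GENES]
    tcga = {g: p for g, _, p in TOP_GENES}
    for i in range(n_decoys):
        n = i % 3  # 0, 1 or 2 cases — all below the recurrence cutoff
        genes.append(f"DECOY{i + 1:02d}")
        rows.append([1] * n + [0] * (7 - n))
    return CohortMatrix(
        genes=tuple(genes),
        cases=COHORT_CASES,
        mutated=np.array(rows, dtype=np.int8),
        tcga_percent=tcga,
    )
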