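"""VAF-based clonality classification.

Under a heterozygous-diploid model at purity 1, a mutation's tumor-cell
fraction is twice its variant allele fraction (capped at 1): a VAF of 50%
means every tumor cell carries the mutation.  Mutations are banded as

* clonal      — VAF >= 0.50
* polyclonal  — 0.20 <= VAF <= 0.45
* subclonal   — VAF < 0.10 (present in < 20% of tumor cells)

The bands deliberately leave (0.10, 0.20) and (0.45, 0.50) uncovered; VAFs
falling there are labeled ``indeterminate`` rather than forced into a
neighboring class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .formats_io import VariantRecord

__all__ = [
    "ClonalityCall",
    "CATEGORIES",
    "tumor_cell_fraction",
    "classify_clonality",
    "gene_clonality",
]

CATEGORIES = ("clonal", "polyclonal", "subclonal", "indeterminate")

CLONAL_MIN = 0.50
POLYCLONAL_MIN = 0.20
POLYCLONAL_MAX = 0.45  # inclusive
SUBCLONAL_MAX = 0.10  # exclusive


@dataclass(frozen=True)
class ClonalityCall:
    vaf: float
    tumor_cell_fraction: float
    category: str


def tumor_cell_fraction(vaf: float) -> float:
    """Fraction of tumor cells carrying a heterozygous mutation: min(2*VAF, 1).

    No purity or copy-number correction is applied.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF {vaf} outside [0, 1]")
    return min(2.0 * vaf, 1.0)


def classify_clonality(vaf: float) -> ClonalityCall:
    """Band a VAF into clonal / polyclonal / subclonal / indeterminate."""
    tcf = tumor_cell_fraction(vaf)  # also validates the range
    if vaf >= CLONAL_MIN:
        category = "clonal"
    elif POLYCLONAL_MIN <= vaf <= POLYCLONAL_MAX:
        category = "polyclonal"
    elif vaf < SUBCLONAL_MAX:
        category = "subclonal"
    else:
        category = "indeterminate"
    return ClonalityCall(vaf=vaf, tumor_cell_fraction=tcf, category=category)


def gene_clonality(
    variants: Iterable[VariantRecord], gene: str, case_id: str
) -> ClonalityCall:
    """Per-gene, per-case clonality from the maximum VAF among the gene's hits.

    A gene is as clonal as its most clonal mutation; one label per
    gene/case.  Raises ``ValueError`` when no variant matches.
    """
    vafs = [v.vaf for v in variants if v.gene == gene and v.case_id == case_id]
    if not vafs:
        raise ValueError(f"no variant of {gene!r} in case {case_id!r}")
    return classify_clonality(max(vafs))
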