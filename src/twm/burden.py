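"""Tumor mutational burden (TMB) metrics and the high-TMB flag.

Whole-genome TMB is mutations per megabase of callable genome; the
whole-exome count converts linearly to a panel-scale m/Mb value anchored at
199 WES mutations = 10 m/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .formats_io import VariantRecord

__all__ = [
    "BurdenSummary",
    "DEFAULT_CALLABLE_MB",
    "WES_PANEL_ANCHOR",
    "compute_wgs_tmb",
    "wes_to_panel_tmb",
    "count_pathogenic",
    "flag_tmb_high",
    "summarize_burden",
]

#: Default callable genome size in Mb for whole-genome TMB.  Per-case
#: callable sizes vary with coverage and filtering (roughly 3.2-3.4 Gb in
#: practice); 3300 Mb sits near the middle and is configuration, not truth.
DEFAULT_CALLABLE_MB = 3300.0

#: The WES count anchoring the panel conversion: 199 exome mutations
#: correspond to a panel TMB of 10 m/Mb.
WES_PANEL_ANCHOR = (199, 10.0)

#: Pathogenic mutations per exome above which a case is flagged high-TMB
#: (strict inequality).
DEFAULT_TMB_HIGH_THRESHOLD = 175


@dataclass(frozen=True)
class BurdenSummary:
    total_mutations: int
    pathogenic_per_exome: int
    wgs_tmb_per_mb: float
    panel_tmb_equiv: float
    tmb_high: bool


def compute_wgs_tmb(total_mutations: int, callable_mb: float = DEFAULT_CALLABLE_MB) -> float:
    """Whole-genome TMB in mutations per Mb of callable genome."""
    if total_mutations < 0:
        raise ValueError("negative mutation count")
    if callable_mb <= 0:
        raise ValueError(f"callable_mb must be positive, got {callable_mb}")
    return total_mutations / callable_mb


def wes_to_panel_tmb(wes_mutation_count: int) -> float:
    """Panel-TMB equivalent (m/Mb) of a whole-exome mutation count.

    Linear through the anchor point: 199 exome mutations <-> 10 m/Mb.
    """
    if wes_mutation_count < 0:
        raise ValueError("negative mutation count")
    anchor_count, anchor_tmb = WES_PANEL_ANCHOR
    return wes_mutation_count * (anchor_tmb / anchor_count)


def count_pathogenic(variants: Iterable[VariantRecord]) -> int:
    """Number of variants flagged pathogenic by upstream annotation."""
    return sum(1 for v in variants if v.pathogenic)


def flag_tmb_high(pathogenic_per_exome: int, threshold: int = DEFAULT_TMB_HIGH_THRESHOLD) -> bool:
    """High-TMB call: strictly more than *threshold* pathogenic mutations."""
    if pathogenic_per_exome < 0:
        raise ValueError("negative count")
    return pathogenic_per_exome > threshold


def summarize_burden(
    total_mutations: int,
    variants: Iterable[VariantRecord],
    callable_mb: float = DEFAULT_CALLABLE_MB,
    tmb_high_threshold: int = DEFAULT_TMB_HIGH_THRESHOLD,
) -> BurdenSummary:
    """Assemble the per-case burden block.

    *total_mutations* is passed separately from *variants* because the
    genome-wide total may include non-SNV calls counted upstream, while the
    pathogenic count is taken from the annotated records at hand.
    """
    pathogenic = count_pathogenic(variants)
    return BurdenSummary(
        total_mutations=total_mutations,
        pathogenic_per_exome=pathogenic,
        wgs_tmb_per_mb=compute_wgs_tmb(total_mutations, callable_mb),
        panel_tmb_equiv=wes_to_panel_tmb(pathogenic),
        tmb_high=flag_tmb_high(pathogenic, tmb_high_threshold),
    )
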