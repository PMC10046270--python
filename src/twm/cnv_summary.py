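"""Copy-number segment categories, LOH genome fraction and the HRD-LOH scar.

Segments carry integer total and minor-allele copy numbers.  Categories,
checked in order of precedence:

* homozygous_loss  — cn_total = 0
* loh              — cn_minor = 0, cn_total >= 1 (copy-neutral LOH and
                     hemizygous loss alike)
* trisomy_gain     — cn_total in {3, 4} with both alleles retained
* amplification    — cn_total >= 5
* neutral          — diploid heterozygous (2/1)

The HRD-LOH score counts LOH segments longer than 15 Mb that do not span a
whole chromosome; ten or more such scars flag the genome as
homologous-recombination deficient.  All thresholds are configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats_io import CnvSegment

__all__ = [
    "CnvCaseSummary",
    "CATEGORY_ORDER",
    "classify_segment",
    "loh_genome_fraction",
    "hrd_loh_score",
    "summarize_cnv_case",
]

CATEGORY_ORDER = ("homozygous_loss", "loh", "trisomy_gain", "amplification", "neutral")

HRD_LOH_MIN_LEN_BP = 15_000_000
HRD_LOH_HIGH_THRESHOLD = 10


@dataclass(frozen=True)
class CnvCaseSummary:
    """Per-case CNV block: category counts, LOH%, HRD-LOH score and flag."""

    n_total: int
    n_amplification: int
    n_trisomy_gain: int
    n_homozygous_loss: int
    n_loh: int
    loh_percent: float
    hrd_loh_score: int
    hrd_high: bool


def classify_segment(
    segment: CnvSegment,
    *,
    amplification_min_cn: int = 5,
    gain_cn: tuple[int, int] = (3, 4),
) -> str:
    """One category per segment, by the precedence listed in the module doc."""
    if segment.cn_total == 0:
        return "homozygous_loss"
    if segment.cn_minor == 0:
        return "loh"
    if gain_cn[0] <= segment.cn_total <= gain_cn[1]:
        return "trisomy_gain"
    if segment.cn_total >= amplification_min_cn:
        return "amplification"
    return "neutral"


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals (sorted, overlaps/adjacency merged)."""
    if not intervals:
        return []
    intervals.sort()
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + 1:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def loh_genome_fraction(
    segments: Iterable[CnvSegment], genome_length_bp: int
) -> float:
    """Percent of the genome under LOH.

    Sums the merged (union) length of LOH-classified segments per
    chromosome, so overlapping or split segments are not double-counted,
    and divides by the total genome length.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        if classify_segment(seg) == "loh":
            by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    total = sum(
        end - start + 1
        for intervals in by_chrom.values()
        for start, end in _merge_intervals(intervals)
    )
    return 100.0 * total / genome_length_bp


def hrd_loh_score(
    segments: Iterable[CnvSegment],
    chrom_lengths: Mapping[str, int],
    min_len_bp: int = HRD_LOH_MIN_LEN_BP,
    high_threshold: int = HRD_LOH_HIGH_THRESHOLD,
) -> tuple[int, bool]:
    """HRD-LOH genomic scar score and the high/low flag.

    Counts LOH segments strictly longer than *min_len_bp* and strictly
    shorter than their chromosome (whole-chromosome LOH reflects aneuploidy,
    not recombination scarring).  ``hrd_high`` is true at or above
    *high_threshold* scars.
    """
    score = 0
    for seg in segments:
        if classify_segment(seg) != "loh":
            continue
        try:
            chrom_len = chrom_lengths[seg.chrom]
        except KeyError as exc:
            raise KeyError(f"no length for chromosome {seg.chrom!r}") from exc
        if seg.length > min_len_bp and seg.length < chrom_len:
            score += 1
    return score, score >= high_threshold


def summarize_cnv_case(
    segments: Sequence[CnvSegment],
    chrom_lengths: Mapping[str, int],
    *,
    min_len_bp: int = HRD_LOH_MIN_LEN_BP,
    high_threshold: int = HRD_LOH_HIGH_THRESHOLD,
) -> CnvCaseSummary:
    """Per-case CNV summary: counts per category, LOH% and the HRD-LOH scar.

    ``n_total`` counts non-neutral segments; the LOH% denominator is the
    genome length implied by *chrom_lengths*.
    """
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for seg in segments:
        counts[classify_segment(seg)] += 1
    genome_length = sum(chrom_lengths.values())
    score, high = hrd_loh_score(
        segments, chrom_lengths, min_len_bp=min_len_bp, high_threshold=high_threshold
    )
    return CnvCaseSummary(
        n_total=sum(v for k, v in counts.items() if k != "neutral"),
        n_amplification=counts["amplification"],
        n_trisomy_gain=counts["trisomy_gain"],
        n_homozygous_loss=counts["homozygous_loss"],
        n_loh=counts["loh"],
        loh_percent=loh_genome_fraction(segments, genome_length),
        hrd_loh_score=score,
        hrd_high=high,
    )
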