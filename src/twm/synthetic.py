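"""Seeded synthetic cohorts with truth records.

Every pipeline stage is testable without access to patient data: this
module generates signature matrices, mutation catalogs drawn from known
exposures, variant tables with designed clonal structure and VAF noise, and
copy-number segment sets with known category truth.

The generative models mirror the analysis assumptions:

* catalogs are multinomial draws from the mixture ``sum_k pi_k s_k``, the
  exact model the EM refit inverts;
* true VAFs sit inside the clonality bands (clonal fixed at 0.50 —
  heterozygous, purity 1), and the observed VAF is a binomial read-count
  draw at configurable depth, so band-crossing noise shrinks as depth
  grows;
* segments are non-overlapping with prescribed classes and lengths on a
  toy genome, the remainder neutral diploid.

Determinism: one global seed; each generator and each case derives an
independent child seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import MutationCatalog
from .formats_io import CHANNELS, CnvSegment, SignatureMatrix, VariantRecord

__all__ = [
    "SyntheticTruth",
    "simulate_signature_matrix",
    "simulate_catalog",
    "simulate_cohort",
    "simulate_segments",
]

_CASE_SEED_STRIDE = 1009  # prime stride keeps per-case streams disjoint


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside generated data."""

    seed: int
    exposures: dict[str, dict[str, float]] = field(default_factory=dict)
    clonality_labels: dict[str, list[str]] = field(default_factory=dict)
    segment_categories: list[str] = field(default_factory=list)


def simulate_signature_matrix(
    k: int, concentration: float = 0.1, seed: int = 0
) -> SignatureMatrix:
    """K random signatures, rows drawn from a symmetric Dirichlet.

    Low *concentration* (default 0.1) gives spiky, well-separated
    signatures like real SBS profiles; a large value approaches uniform.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(96, concentration), size=k)
    ids = [f"SYN{i + 1}" for i in range(k)]
    return SignatureMatrix(ids, probs)


def simulate_catalog(
    signatures: SignatureMatrix,
    exposures: Sequence[float],
    n: int,
    seed: int = 0,
    case_id: str = "sim",
) -> MutationCatalog:
    """Catalog of *n* channel draws from the mixture ``sum_k pi_k s_k``."""
    pi = np.asarray(exposures, dtype=float)
    if pi.shape != (signatures.k,):
        raise ValueError("exposures length does not match signature count")
    if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("exposures must be non-negative and sum to 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    mix = pi @ signatures.probs
    counts = rng.multinomial(n, mix) if n > 0 else np.zeros(96, dtype=np.int64)
    return MutationCatalog(counts=counts, case_id=case_id)


def _channel_to_variant_fields(channel: str) -> tuple[str, str, str, str]:
    """(ref, alt, ctx5, ctx3) on the pyrimidine strand for a channel label."""
    # label layout: "A[C>T]G"
    return channel[2], channel[4], channel[0], channel[6]


_CLONALITY_CLASSES = ("clonal", "polyclonal", "subclonal")


def simulate_cohort(
    n_cases: int,
    n_variants_per_case: int,
    clonal_mix: Sequence[float] = (0.5, 0.3, 0.2),
    depth: int | None = 60,
    seed: int = 0,
    *,
    signatures: SignatureMatrix | None = None,
    exposures: Sequence[float] | None = None,
    gene_pool: Sequence[str] = ("TERT", "TTN", "MUC4", "PCLO", "ZFHX4", "CSMD1", "RELN"),
    pathogenic_rate: float = 0.1,
) -> tuple[dict[str, list[VariantRecord]], SyntheticTruth]:
    """Variant tables for *n_cases* synthetic cases with clonality truth.

    Per variant a true category is drawn from *clonal_mix* over
    (clonal, polyclonal, subclonal); the true VAF is 0.50 for clonal,
    uniform on [0.20, 0.45] for polyclonal and uniform on [0.01, 0.0999]
    for subclonal.  The observed VAF is ``Binomial(depth, vaf)/depth``;
    ``depth=None`` is the infinite-depth mode (observed = true).

    When *signatures*/*exposures* are given, each variant's channel is drawn
    from the implied mixture and its ref/alt/context fields are set from
    the channel label, so ``build_catalog`` on a case's table reproduces a
    catalog drawn from those exposures.  Otherwise channels are uniform.
    """
    mix = np.asarray(clonal_mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("clonal_mix must be 3 non-negative fractions summing to 1")
    if signatures is not None:
        if exposures is None:
            raise ValueError("exposures required when signatures are given")
        pi = np.asarray(exposures, dtype=float)
        channel_probs = pi @ signatures.probs
    else:
        channel_probs = np.full(96, 1.0 / 96)

    tables: dict[str, list[VariantRecord]] = {}
    truth = SyntheticTruth(seed=seed)
    for i in range(n_cases):
        case_id = f"case{i + 1}"
        rng = np.random.default_rng(seed + _CASE_SEED_STRIDE * (i + 1))
        cats = rng.choice(3, size=n_variants_per_case, p=mix)
        true_vaf = np.empty(n_variants_per_case)
        true_vaf[cats == 0] = 0.50
        true_vaf[cats == 1] = rng.uniform(0.20, 0.45, size=int((cats == 1).sum()))
        true_vaf[cats == 2] = rng.uniform(0.01, 0.0999, size=int((cats == 2).sum()))
        if depth is None:
            obs_vaf = true_vaf
        else:
            obs_vaf = rng.binomial(depth, true_vaf) / depth
        channels = rng.choice(96, size=n_variants_per_case, p=channel_probs)
        genes = rng.choice(len(gene_pool), size=n_variants_per_case)
        patho = rng.random(n_variants_per_case) < pathogenic_rate
        records = []
        for j in range(n_variants_per_case):
            ref, alt, ctx5, ctx3 = _channel_to_variant_fields(CHANNELS[channels[j]])
            records.append(
                VariantRecord(
                    case_id=case_id,
                    chrom="chr1",
                    pos=1000 + 10 * j,
                    ref=ref,
                    alt=alt,
                    vaf=float(obs_vaf[j]),
                    gene=str(gene_pool[genes[j]]),
                    pathogenic=bool(patho[j]),
                    ctx5=ctx5,
                    ctx3=ctx3,
                )
            )
        tables[case_id] = records
        truth.clonality_labels[case_id] = [_CLONALITY_CLASSES[c] for c in cats]
        if signatures is not None:
            truth.exposures[case_id] = {
                s: float(p) for s, p in zip(signatures.signature_ids, exposures)
            }
    return tables, truth


_CLASS_CN = {
    "loh": (2, 0),  # copy-neutral LOH
    "trisomy_gain": (3, 1),
    "homozygous_loss": (0, 0),
    "amplification": (6, 1),
}


def simulate_segments(
    chrom_lengths: Mapping[str, int],
    n_loh: int = 0,
    loh_len_bp: int = 20_000_000,
    n_gain: int = 0,
    n_hl: int = 0,
    seed: int = 0,
    *,
    n_amp: int = 0,
    gain_len_bp: int = 10_000_000,
    hl_len_bp: int = 1_000_000,
    amp_len_bp: int = 2_000_000,
    fill_neutral: bool = True,
) -> tuple[list[CnvSegment], SyntheticTruth]:
    """Non-overlapping segments with prescribed classes on a toy genome.

    Event segments (LOH, gain, homozygous loss, amplification) are packed
    left to right across chromosomes in a seeded random class order; the
    uncovered remainder is emitted as neutral diploid segments when
    *fill_neutral* is set.  Raises ``ValueError`` when the requested events
    do not fit.
    """
    rng = np.random.default_rng(seed)
    wanted = (
        ["loh"] * n_loh + ["trisomy_gain"] * n_gain
        + ["homozygous_loss"] * n_hl + ["amplification"] * n_amp
    )
    rng.shuffle(wanted)
    lengths = {
        "loh": loh_len_bp, "trisomy_gain": gain_len_bp,
        "homozygous_loss": hl_len_bp, "amplification": amp_len_bp,
    }
    segments: list[CnvSegment] = []
    truth = SyntheticTruth(seed=seed)
    chroms = list(chrom_lengths.items())
    ci = 0
    cursor = 1
    for cls in wanted:
        length = lengths[cls]
        while ci < len(chroms) and cursor + length - 1 > chroms[ci][1]:
            ci += 1
            cursor = 1
        if ci >= len(chroms):
            raise ValueError("requested segments do not fit on the toy genome")
        chrom = chroms[ci][0]
        cn_total, cn_minor = _CLASS_CN[cls]
        segments.append(
            CnvSegment(chrom=chrom, start=cursor, end=cursor + length - 1,
                       cn_total=cn_total, cn_minor=cn_minor)
        )
        truth.segment_categories.append(cls)
        cursor += length
    if fill_neutral:
        covered: dict[str, list[CnvSegment]] = {}
        for seg in segments:
            covered.setdefault(seg.chrom, []).append(seg)
        for chrom, chrom_len in chroms:
            pos = 1
            for seg in sorted(covered.get(chrom, []), key=lambda s: s.start):
                if seg.start > pos:
                    segments.append(CnvSegment(chrom, pos, seg.start - 1, 2, 1))
                    truth.segment_categories.append("neutral")
                pos = seg.end + 1
            if pos <= chrom_len:
                segments.append(CnvSegment(chrom, pos, chrom_len, 2, 1))
                truth.segment_categories.append("neutral")
    return segments, truth
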