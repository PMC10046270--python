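"""Readers and writers for the variant, signature and copy-number formats.

Every downstream stage consumes only the types defined here:

* :class:`VariantRecord` — one somatic single-nucleotide variant with its
  variant allele fraction (VAF), gene symbol, pathogenicity flag and the
  immediate 5'/3' reference context bases.
* :class:`SignatureMatrix` — a K x 96 row-stochastic matrix of single-base
  substitution (SBS) signature probabilities in the canonical 96-channel
  trinucleotide layout.
* :class:`CnvSegment` — an allele-specific copy-number segment with total
  and minor integer copy numbers.

Coordinates are 1-based inclusive throughout (VCF convention).  Segment
tables written by 0-based upstream tools can be shifted on read with
``zero_based=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "SignatureMatrix",
    "CnvSegment",
    "ReadReport",
    "read_variant_table",
    "write_variant_table",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_segments",
    "write_segments",
    "extract_context",
    "CHANNELS",
    "CHANNEL_INDEX",
    "BASES",
    "COMPLEMENT",
]

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: Placeholder for a context base that could not be determined (contig edge).
UNKNOWN_BASE = "N"

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical 96-channel order: substitutions C>A, C>G, C>T, T>A, T>C, T>G;
#: within each substitution the 5' then the 3' base cycle through A,C,G,T.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS)}


@dataclass(frozen=True)
class VariantRecord:
    """A single somatic SNV with the per-mutation attributes the pipeline uses.

    ``ctx5`` / ``ctx3`` are the immediate 5' and 3' reference bases; ``"N"``
    marks an unknown context (e.g. a contig edge).
    """

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    gene: str = ""
    pathogenic: bool = False
    ctx5: str = UNKNOWN_BASE
    ctx3: str = UNKNOWN_BASE

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT ref/alt {self.ref}>{self.alt}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1 (coordinates are 1-based)")

    @property
    def has_context(self) -> bool:
        return self.ctx5 in BASES and self.ctx3 in BASES


@dataclass(frozen=True)
class CnvSegment:
    """Allele-specific copy-number segment, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.cn_total < 0 or self.cn_minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.cn_minor > self.cn_total - self.cn_minor:
            raise ValueError(
                f"cn_minor {self.cn_minor} exceeds the major allele for "
                f"cn_total {self.cn_total}; minor must be the lesser allele"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class SignatureMatrix:
    """K x 96 row-stochastic SBS signature probabilities.

    Rows are signatures (``signature_ids``), columns the 96 canonical
    trinucleotide channels.  Row ``k``, column ``c`` is the probability
    ``s_kc`` that a mutation generated by signature ``k`` falls in channel
    ``c``.
    """

    def __init__(self, signature_ids: Sequence[str], probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 96:
            raise ValueError(f"expected K x 96 matrix, got shape {probs.shape}")
        if len(signature_ids) != probs.shape[0]:
            raise ValueError("signature_ids length does not match matrix rows")
        if len(set(signature_ids)) != len(signature_ids):
            raise ValueError("duplicate signature ids")
        if (probs < 0).any():
            raise ValueError("negative signature probability")
        sums = probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-4
        if bad.any():
            offender = list(signature_ids)[int(np.argmax(bad))]
            raise ValueError(f"signature {offender} row sums to {sums[bad][0]:.6f}, not 1")
        self.signature_ids: tuple[str, ...] = tuple(signature_ids)
        # renormalize away float noise below the 1e-4 gate
        self.probs: np.ndarray = probs / sums[:, None]
        self.channel_labels: tuple[str, ...] = CHANNELS

    @property
    def k(self) -> int:
        return len(self.signature_ids)

    def subset(self, ids: Sequence[str]) -> "SignatureMatrix":
        idx = [self.signature_ids.index(s) for s in ids]
        return SignatureMatrix([self.signature_ids[i] for i in idx], self.probs[idx])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SignatureMatrix(K={self.k}, ids={list(self.signature_ids)!r})"


@dataclass
class ReadReport:
    """Skip/reject accounting emitted alongside every reader's output."""

    n_read: int = 0
    n_kept: int = 0
    n_skipped_non_snv: int = 0
    n_rejected: int = 0


_VARIANT_COLUMNS = [
    "case_id", "chrom", "pos", "ref", "alt", "vaf", "gene", "pathogenic", "ctx5", "ctx3",
]


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES and ref != alt


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    *,
    case_id: str | None = None,
    sample: str | None = None,
    report: ReadReport | None = None,
) -> list[VariantRecord]:
    """Read somatic variants from a TSV table or a VCF file.

    Only biallelic SNVs become :class:`VariantRecord`; indels, MNVs and
    multi-allelic records are skipped and counted in *report*.  Records with
    a VAF outside [0, 1] are rejected and counted.

    For the VCF dialect the VAF is taken from the tumor sample's ``AF``
    FORMAT field when present, otherwise computed as alt depth over total
    depth from ``AD``.  *sample* selects the tumor sample by name (default:
    the first sample).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if report is None:
        report = ReadReport()
    if dialect == "tsv":
        return _read_variant_tsv(path, report)
    if dialect == "vcf":
        return _read_variant_vcf(path, report, case_id=case_id or path.stem, sample=sample)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _read_variant_tsv(path: Path, report: ReadReport) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    out: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        report.n_read += 1
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if not _is_snv(ref, alt):
            report.n_skipped_non_snv += 1
            continue
        try:
            rec = VariantRecord(
                case_id=str(row.case_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                vaf=float(row.vaf),
                gene=str(row.gene),
                pathogenic=str(row.pathogenic).strip().lower() in ("true", "1", "yes"),
                ctx5=str(row.ctx5).upper() or UNKNOWN_BASE,
                ctx3=str(row.ctx3).upper() or UNKNOWN_BASE,
            )
        except (ValueError, TypeError) as exc:
            log.warning("rejected record at %s:%s: %s", row.chrom, row.pos, exc)
            report.n_rejected += 1
            continue
        out.append(rec)
        report.n_kept += 1
    if report.n_skipped_non_snv or report.n_rejected:
        log.info(
            "%s: kept %d SNVs, skipped %d non-SNV, rejected %d invalid",
            path, report.n_kept, report.n_skipped_non_snv, report.n_rejected,
        )
    return out


def _read_variant_vcf(
    path: Path, report: ReadReport, case_id: str, sample: str | None
) -> list[VariantRecord]:
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample is not None and sample not in samples:
            raise ValueError(f"sample {sample!r} not in VCF ({samples})")
        use = sample or (samples[0] if samples else None)
        for rec in vcf:
            report.n_read += 1
            alts = rec.alts or ()
            if len(alts) != 1 or not _is_snv(rec.ref or "", alts[0] or ""):
                report.n_skipped_non_snv += 1
                continue
            vaf = _vcf_vaf(rec, use)
            if vaf is None:
                report.n_rejected += 1
                continue
            gene = _info_field(rec, "GENE", "")
            if isinstance(gene, tuple):
                gene = gene[0] if gene else ""
            try:
                variant = VariantRecord(
                    case_id=case_id,
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref).upper(),
                    alt=str(alts[0]).upper(),
                    vaf=float(vaf),
                    gene=str(gene or ""),
                    pathogenic=bool(_info_field(rec, "PATHOGENIC", False)),
                )
            except ValueError as exc:
                log.warning("rejected VCF record %s:%d: %s", rec.chrom, rec.pos, exc)
                report.n_rejected += 1
                continue
            out.append(variant)
            report.n_kept += 1
    return out


def _info_field(rec, key: str, default):
    """INFO lookup tolerant of keys absent from the VCF header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _vcf_vaf(rec, sample: str | None) -> float | None:
    """Tumor VAF: sample AF field first, else alt/total from AD, else INFO AF."""
    if sample is not None:
        fmt = rec.samples[sample]
        af = fmt.get("AF")
        if af is not None:
            value = af[0] if isinstance(af, tuple) else af
            if value is not None:
                return float(value)
        ad = fmt.get("AD")
        if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
            total = sum(d for d in ad if d is not None)
            if total > 0:
                return float(ad[1]) / total
    info_af = _info_field(rec, "AF", None)
    if info_af is not None:
        value = info_af[0] if isinstance(info_af, tuple) else info_af
        if value is not None:
            return float(value)
    return None


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    """Write the TSV dialect read back by :func:`read_variant_table`."""
    rows = [
        {
            "case_id": v.case_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "vaf": repr(v.vaf), "gene": v.gene,
            "pathogenic": str(v.pathogenic).lower(), "ctx5": v.ctx5, "ctx3": v.ctx3,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a signature matrix in the COSMIC distribution layout.

    The file is a TSV with 96 channel rows (first column ``Type`` holding
    labels like ``A[C>A]A``) and one column per signature.  The matrix is
    transposed to K x 96 in canonical channel order; columns summing within
    1e-4 of 1 are renormalized, anything further off is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    labels = [str(x) for x in df[label_col]]
    seen = set()
    for lab in labels:
        if lab not in CHANNEL_INDEX:
            raise ValueError(f"{path}: unknown channel label {lab!r}")
        if lab in seen:
            raise ValueError(f"{path}: duplicate channel {lab!r}")
        seen.add(lab)
    missing = [lab for lab in CHANNELS if lab not in seen]
    if missing:
        raise ValueError(f"{path}: missing channel(s), first absent: {missing[0]!r}")
    order = np.argsort([CHANNEL_INDEX[lab] for lab in labels])
    sig_ids = [str(c) for c in df.columns[1:]]
    if not sig_ids:
        raise ValueError(f"{path}: no signature columns")
    probs = df[df.columns[1:]].to_numpy(dtype=float)[order].T  # K x 96
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0) > 1e-4
    if off.any():
        offender = sig_ids[int(np.argmax(off))]
        raise ValueError(
            f"{path}: signature {offender} sums to {sums[off][0]:.6f} (off by >1e-4)"
        )
    return SignatureMatrix(sig_ids, probs)


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    """Write the COSMIC-layout TSV read back by :func:`read_signature_matrix`."""
    df = pd.DataFrame({"Type": list(CHANNELS)})
    for i, sid in enumerate(matrix.signature_ids):
        df[sid] = matrix.probs[i]
    df.to_csv(path, sep="\t", index=False)


def read_segments(
    path: str | Path,
    *,
    zero_based: bool = False,
    report: ReadReport | None = None,
) -> list[CnvSegment]:
    """Read allele-specific copy-number segments from a TSV.

    Expects columns ``chrom, start, end, cn_total, cn_minor``.  Rows
    violating the segment invariants (start > end, minor allele larger than
    the major) are rejected and counted in *report*.  ``zero_based=True``
    shifts 0-based half-open starts to the internal 1-based inclusive
    convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if report is None:
        report = ReadReport()
    df = pd.read_csv(path, sep="\t")
    needed = ["chrom", "start", "end", "cn_total", "cn_minor"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing segment columns {missing}")
    out: list[CnvSegment] = []
    for row in df.itertuples(index=False):
        report.n_read += 1
        start = int(row.start) + (1 if zero_based else 0)
        try:
            seg = CnvSegment(
                chrom=str(row.chrom), start=start, end=int(row.end),
                cn_total=int(row.cn_total), cn_minor=int(row.cn_minor),
            )
        except ValueError as exc:
            log.warning("rejected segment %s:%s-%s: %s", row.chrom, row.start, row.end, exc)
            report.n_rejected += 1
            continue
        out.append(seg)
        report.n_kept += 1
    return out


def write_segments(segments: Iterable[CnvSegment], path: str | Path) -> None:
    rows = [
        {"chrom": s.chrom, "start": s.start, "end": s.end,
         "cn_total": s.cn_total, "cn_minor": s.cn_minor}
        for s in segments
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_total", "cn_minor"]).to_csv(
        path, sep="\t", index=False
    )


def extract_context(
    chrom: str, pos: int, reference: Mapping[str, str]
) -> tuple[str, str]:
    """Immediate 5' and 3' reference bases flanking a 1-based position.

    *reference* is any mapping from contig name to an indexable sequence
    (a plain dict of strings, or a ``pyfaidx.Fasta``).  Positions at contig
    edges return ``"N"`` for the missing side; an absent contig is fatal.
    """
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} absent from reference") from exc
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside contig {chrom!r} (length {n})")
    ctx5 = str(seq[pos - 2]).upper() if pos >= 2 else UNKNOWN_BASE
    ctx3 = str(seq[pos]).upper() if pos <= n - 1 else UNKNOWN_BASE
    return ctx5, ctx3


def annotate_contexts(
    variants: Iterable[VariantRecord], reference: Mapping[str, str]
) -> list[VariantRecord]:
    """Return copies of *variants* with ctx5/ctx3 filled from *reference*."""
    out = []
    for v in variants:
        ctx5, ctx3 = extract_context(v.chrom, v.pos, reference)
        out.append(replace(v, ctx5=ctx5, ctx3=ctx3))
    return out
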