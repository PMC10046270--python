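"""Per-case and cohort report composition.

Chains the pipeline stages — catalog building, EM signature refit, etiology
banding, burden metrics, CNV/LOH/HRD summary — into one deterministic
per-case report, and aggregates cases into a cohort report with the
recurrence and over-representation gene lists plus a per-gene clonality
table.

The per-case JSON layout is published as ``data/case_report.schema.json``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

from .burden import BurdenSummary, summarize_burden
from .catalog import build_catalog
from .clonality import classify_clonality
from .cnv_summary import CnvCaseSummary, summarize_cnv_case
from .cohort import (
    CohortMatrix,
    build_matrix,
    incidence_percent,
    overrepresented_genes,
    recurrent_genes,
)
from .formats_io import CnvSegment, SignatureMatrix, VariantRecord
from .signature_fit import EtiologySummary, em_fit, etiology_summary

__all__ = ["CaseReport", "run_case", "run_cohort"]


@dataclass
class CaseReport:
    """One case's full analysis block."""

    case_id: str
    burden: BurdenSummary
    etiology: EtiologySummary
    exposures: dict[str, float]
    cnv: CnvCaseSummary
    msi_status: str = "unknown"  # pass-through metadata: MSS / MSI / unknown
    n_catalog: int = 0
    n_skipped_no_context: int = 0

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "burden": dataclasses.asdict(self.burden),
            "etiology": dataclasses.asdict(self.etiology),
            "exposures": self.exposures,
            "cnv": dataclasses.asdict(self.cnv),
            "msi_status": self.msi_status,
            "n_catalog": self.n_catalog,
            "n_skipped_no_context": self.n_skipped_no_context,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_case(
    variants: Sequence[VariantRecord],
    segments: Sequence[CnvSegment],
    signatures: SignatureMatrix,
    chrom_lengths: Mapping[str, int],
    *,
    case_id: str | None = None,
    total_mutations: int | None = None,
    msi_status: str = "unknown",
    callable_mb: float | None = None,
    prune: bool = True,
) -> CaseReport:
    """Deterministic per-case composition of all analysis stages.

    *total_mutations* defaults to the number of variant records (pass the
    genome-wide total explicitly when the records at hand are a pathogenic
    subset).  Stage errors propagate with the stage name prefixed.
    """
    cid = case_id or (variants[0].case_id if variants else "case")
    try:
        catalog = build_catalog(variants, case_id=cid)
    except Exception as exc:
        raise RuntimeError(f"catalog stage failed for {cid}: {exc}") from exc
    try:
        exposures = em_fit(catalog, signatures, prune=prune)
        etiology = etiology_summary(exposures)
    except Exception as exc:
        raise RuntimeError(f"signature stage failed for {cid}: {exc}") from exc
    try:
        kwargs = {} if callable_mb is None else {"callable_mb": callable_mb}
        burden = summarize_burden(
            total_mutations if total_mutations is not None else len(variants),
            variants,
            **kwargs,
        )
    except Exception as exc:
        raise RuntimeError(f"burden stage failed for {cid}: {exc}") from exc
    try:
        cnv = summarize_cnv_case(segments, chrom_lengths)
    except Exception as exc:
        raise RuntimeError(f"cnv stage failed for {cid}: {exc}") from exc
    return CaseReport(
        case_id=cid,
        burden=burden,
        etiology=etiology,
        exposures=exposures.as_dict(),
        cnv=cnv,
        msi_status=msi_status,
        n_catalog=catalog.total,
        n_skipped_no_context=catalog.n_skipped_no_context,
    )


def run_cohort(
    variant_tables: Mapping[str, Sequence[VariantRecord]],
    reference_percents: Mapping[str, float] | None = None,
    *,
    min_cases_exclusive: int = 2,
    fold: float = 2.0,
) -> dict:
    """Cohort report: recurrence list, incidences, over-representation, clonality.

    *variant_tables* maps case id to that case's variant records; case ids
    inside the records must match their table's key.
    """
    cases = list(variant_tables)
    all_variants: list[VariantRecord] = []
    for cid, table in variant_tables.items():
        for v in table:
            if v.case_id != cid:
                raise ValueError(
                    f"variant case id {v.case_id!r} inconsistent with table {cid!r}"
                )
            all_variants.append(v)
    matrix = build_matrix(all_variants, cases)
    if reference_percents:
        matrix.tcga_percent = dict(reference_percents)
    recurrent = recurrent_genes(matrix, min_cases_exclusive)
    over = overrepresented_genes(matrix, fold) if reference_percents else []
    incidences = {
        g: incidence_percent(matrix.n_cases_mutated(g), len(cases)) for g in matrix.genes
    }
    # per-gene/case clonality from the max-VAF rule (one label per hit cell)
    clonality_rows = []
    best: dict[tuple[str, str], float] = {}
    for v in all_variants:
        if not v.gene:
            continue
        key = (v.case_id, v.gene)
        if key not in best or v.vaf > best[key]:
            best[key] = v.vaf
    for (cid, gene), vaf in sorted(best.items()):
        call = classify_clonality(vaf)
        clonality_rows.append(
            {
                "case_id": cid,
                "gene": gene,
                "max_vaf": vaf,
                "tumor_cell_fraction": call.tumor_cell_fraction,
                "category": call.category,
            }
        )
    return {
        "cases": cases,
        "recurrent_genes": recurrent,
        "incidence_percent": incidences,
        "overrepresented_genes": over,
        "clonality": clonality_rows,
    }
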