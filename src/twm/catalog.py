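"""Trinucleotide mutation catalogs.

Maps each SNV to its pyrimidine-strand trinucleotide channel and aggregates
per-case 96-channel count vectors, the input to signature refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .formats_io import BASES, CHANNELS, CHANNEL_INDEX, COMPLEMENT, VariantRecord

__all__ = ["MutationCatalog", "channel_of", "build_catalog", "write_catalog", "read_catalog"]


@dataclass
class MutationCatalog:
    """Per-case 96-channel mutation counts ``n_c`` in canonical order."""

    counts: np.ndarray
    case_id: str = ""
    n_skipped_no_context: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"expected 96 counts, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        """Total mutations in the catalog, N = sum of channel counts."""
        return int(self.counts.sum())

    def __getitem__(self, channel: str) -> int:
        return int(self.counts[CHANNEL_INDEX[channel]])


def channel_of(ref: str, alt: str, ctx5: str, ctx3: str) -> str:
    """Canonical 96-channel label for a substitution in its context.

    Channels are defined on the pyrimidine strand: a purine reference
    (A or G) is reverse-complemented, which also swaps and complements the
    flanking bases, e.g. G>A with 5' T and 3' G becomes C[C>T]A.
    """
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    for b in (ref, alt, ctx5, ctx3):
        if b not in BASES:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        ctx5, ctx3 = COMPLEMENT[ctx3], COMPLEMENT[ctx5]
    return f"{ctx5}[{ref}>{alt}]{ctx3}"


def build_catalog(variants: Iterable[VariantRecord], case_id: str = "") -> MutationCatalog:
    """Tally variants into a 96-channel catalog.

    Variants with unknown context bases cannot be assigned a channel; they
    are skipped and counted in ``n_skipped_no_context`` (they still count
    toward mutation burden, which needs no context).
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for v in variants:
        if not v.has_context:
            skipped += 1
            continue
        counts[CHANNEL_INDEX[channel_of(v.ref, v.alt, v.ctx5, v.ctx3)]] += 1
    return MutationCatalog(counts=counts, case_id=case_id, n_skipped_no_context=skipped)


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    """Two-column TSV (channel, count) in canonical channel order."""
    pd.DataFrame({"channel": list(CHANNELS), "count": catalog.counts}).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path: str | Path, case_id: str = "") -> MutationCatalog:
    df = pd.read_csv(path, sep="\t")
    if list(df["channel"]) != list(CHANNELS):
        raise ValueError(f"{path}: channels not in canonical order")
    return MutationCatalog(counts=df["count"].to_numpy(dtype=np.int64), case_id=case_id)
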