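# twm — post-variant-calling analysis of triple-wild-type cutaneous melanoma

About 80% of common cutaneous melanomas carry a mutant BRAF, RAS-family or
KIT driver. The remainder — **triple-wild-type melanoma (TWM)** in the
BRAF/RAS/KIT sense — is genetically heterogeneous, frequently driverless at
first sight, and is characterized through genome-wide summary statistics
rather than a single driver test. This package implements that downstream
analysis layer for whole-genome-sequenced tumor/normal pairs, starting from
already-called and annotated somatic variants and copy-number segments:

* **96-channel trinucleotide mutation catalogs** — each SNV is mapped to its
  pyrimidine-strand substitution-in-context channel (`A[C>T]G`, …).
* **COSMIC signature refitting by expectation–maximization** — exposures
  π of a fixed K×96 signature matrix S are fitted to a catalog n by
  maximizing `ℓ(π) = Σ_c n_c log(Σ_k π_k s_kc)`, with per-mutation posterior
  attribution and a UV call (`Σ posterior over SBS7a/b/c/d + SBS38 ≥ 0.5`),
  plus qualitative etiology bands (UV predominant/minor, APOBEC flag, SBS3
  HRD band).
* **Tumor mutational burden** — WGS-TMB as mutations per callable Mb
  (default 3300 Mb), and a linear WES→panel conversion anchored at
  199 exome mutations = 10 m/Mb, with a high-TMB flag (> 175 pathogenic
  mutations per exome).
* **VAF clonality classes** — tumor-cell fraction `min(2·VAF, 1)` under a
  heterozygous-diploid purity-1 model; clonal (VAF ≥ 0.50), polyclonal
  (0.20–0.45), subclonal (< 0.10), indeterminate in the gaps; one label per
  gene/case by the max-VAF rule.
* **CNV, LOH and HRD scars** — segment categories from allele-specific
  integer copy numbers (amplification ≥ 5, trisomy-like gain 3–4,
  homozygous loss 0, LOH when the minor allele is lost), the LOH genome
  fraction, and an HRD-LOH score counting sub-chromosomal LOH scars
  > 15 Mb (high at ≥ 10).
* **Cohort statistics** — gene-by-case matrix, half-up incidence percents,
  a strict `> 2 cases` recurrence filter and a two-fold over-representation
  filter against reference (TCGA-SKCM) incidences.
* **Seeded synthetic cohorts** (`twm.synthetic`) — catalogs drawn from
  known exposures, variant tables with designed clonal structure and
  binomial VAF noise, segment sets with category truth — so every stage is
  testable without patient data.

A seven-case TWM reference cohort's published summary tables (mutation
totals, pathogenic counts, TMB, top-gene incidences with TCGA percents) are
bundled in `twm.datasets` as structured inputs for the cohort filters.

## Worked example

Simulate a UV-dominated case (2,000 SNVs drawn from 55/25/15/5% exposures
on SBS7a/SBS7b/SBS5/SBS1-labeled profiles; two 20 Mb LOH segments and one
trisomy on a 200 Mb toy genome) and run the full per-case report:

```python
from twm.formats_io import SignatureMatrix
from twm.synthetic import simulate_signature_matrix, simulate_cohort, simulate_segments
from twm.report import run_case

MB = 1_000_000
base = simulate_signature_matrix(4, seed=7)
sigs = SignatureMatrix(["SBS7a", "SBS7b", "SBS5", "SBS1"], base.probs)
tables, truth = simulate_cohort(
    1, 2_000, depth=None, seed=11, signatures=sigs, exposures=[0.55, 0.25, 0.15, 0.05]
)
lengths = {"chr1": 100 * MB, "chr2": 100 * MB}
segments, _ = simulate_segments(lengths, n_loh=2, loh_len_bp=20 * MB, n_gain=1, seed=13)
print(run_case(tables["case1"], segments, sigs, lengths, msi_status="MSS").to_json())
```

prints (abridged):

```json
{
  "cnv": {"hrd_high": false, "hrd_loh_score": 2, "loh_percent": 20.0,
          "n_loh": 2, "n_total": 3, "n_trisomy_gain": 1},
  "etiology": {"apobec_flag": false, "hrd_band": "none",
               "uv_band": "predominant", "uv_share": 0.7874880970100311},
  "exposures": {"SBS1": 0.0505, "SBS5": 0.1620, "SBS7a": 0.5377, "SBS7b": 0.2498},
  "msi_status": "MSS"
}
```

The EM refit recovers the designated exposures (0.538/0.250/0.162/0.051 vs
the true 0.55/0.25/0.15/0.05 at N = 2,000), the UV share 0.79 bands the
case "predominant", and the two 20 Mb LOH segments give 20% of the toy
genome under LOH and two HRD-LOH scars (below the high threshold of 10).

The same stages are scriptable from a shell via the `twm` CLI
(`twm catalog`, `twm fit`, `twm attribute`, `twm tmb`, `twm clonality`,
`twm cnv`, `twm cohort`, `twm simulate`, `twm report`); run
`twm --help` for the subcommand surface.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package's own operations, the panel-TMB
equivalent of a 199-mutation exome count, the tumor-cell fractions at the
50% and 10% VAF landmarks, and the size of the recurrence-filtered gene
list on the bundled seven-case reference matrix (with decoy genes below
the threshold), and writes them as JSON.
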