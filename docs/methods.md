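# Methods

## Scope and model of the data

The package operates strictly downstream of variant calling: inputs are
per-case somatic variant tables (TSV or VCF 4.x) with VAF, gene symbol and
a pathogenicity flag already attached by upstream annotation, plus
allele-specific copy-number segment tables and a fixed SBS signature
probability matrix. Alignment, calling, functional annotation, MSI calling
and CNV segmentation are consumed, never computed. Coordinates are 1-based
inclusive everywhere; segment files from 0-based upstream tools are shifted
on read (`zero_based=True` / `--zero-based-segments`).

Only biallelic SNVs enter the 96-channel analysis; indels/MNVs are skipped
with logged counts (the trinucleotide scheme is SNV-only), but the burden
total is an explicit argument so the caller can count them if their
upstream total does. VAF in VCFs is taken from the tumor sample's `AF`
FORMAT field, else alt/total depths from `AD`, else an INFO `AF` — matching
common somatic-caller output without binding to one caller.

## Trinucleotide channels

The 96 channels are the six pyrimidine substitutions (C>A, C>G, C>T, T>A,
T>C, T>G) crossed with the 5' and 3' flanking bases in A,C,G,T order. A
purine reference is reverse-complemented, swapping and complementing the
flanks, so both strand descriptions of one event map to one channel
(property-tested involution). Variants with unknown context (contig edges)
are excluded from catalogs but not from burden counts: a channel is
undefined without context; TMB needs no context.

## Signature refitting

The catalog is modeled as N draws from the mixture `Σ_k π_k s_k·` with the
signature matrix fixed (refitting, not extraction — no NMF, no confidence
intervals). EM from a uniform start:

    r_kc = π_k s_kc / Σ_j π_j s_jc        (responsibilities)
    π_k ← Σ_c n_c r_kc / N                (update)

The log-likelihood is concave in the mixture distribution, so the fit is
insensitive to the start and no restarts are used (determinism).
Convergence is an absolute log-likelihood improvement below `tol = 1e-8`,
capped at 10,000 iterations with `converged=False` if hit; the
per-iteration likelihood trace is kept on the result for monotonicity
diagnostics. With pruning (default on), signatures ending below
`prune_threshold = 0.01` are dropped and the fit repeated once on the
reduced set, reported at exposure 0 — standard refitting practice for a
candidate list such as the melanoma set SBS1/2/3/5/7a–d/13/17a/17b/38/40.

Per-mutation attribution reuses the responsibilities at the fitted π; the
UV posterior sums SBS7a–d and SBS38 and a mutation is called UV-related at
`uv_posterior ≥ 0.5` (ties called UV). The doublet signature DBS1 is also
UV-associated but lives outside the SBS space and is excluded from this
SNV-only pipeline.

Etiology bands turn exposures into the qualitative vocabulary of a per-case
summary table: UV "predominant" at share ≥ 0.5 else "minor"; APOBEC flag
at SBS2+SBS13 ≥ 0.10; HRD band from SBS3 — none < 0.05, minor 0.05–0.20,
present > 0.20. The source analyses report only the qualitative bands, so
the cutoffs are package configuration with these defaults.

## Burden

WGS-TMB is `total_mutations / callable_mb`. Published per-case TMBs imply
callable sizes of roughly 3.22–3.36 Gb that were not themselves published,
so the divisor is configuration with default 3300 Mb, near the cohort
center; published TMBs are then reproduced from published totals to within
3%, not exactly. The WES→panel conversion is linear through the anchor
199 mutations = 10 m/Mb. The high-TMB flag is strictly more than 175
pathogenic mutations per exome — the threshold's published phrasing
conflates a count and a rate, so both the value and its interpretation are
exposed as configuration rather than hard-coded intent.

## Clonality

Tumor-cell fraction is `min(2·VAF, 1)`: heterozygous, diploid, purity 1, no
copy-number correction (the arithmetic that equates VAF 50% with 100% of
tumor cells). Bands: clonal VAF ≥ 0.50; polyclonal 0.20–0.45 (upper bound
read as inclusive); subclonal < 0.10. The published bands leave
(0.10, 0.20) and (0.45, 0.50) undefined; an explicit `indeterminate`
category preserves the printed boundaries instead of inventing coverage.
Genes get one label per case from their maximum-VAF mutation — a gene is as
clonal as its most clonal hit.

## CNV, LOH and HRD

Categories from integer allele-specific copy numbers, in precedence order:
homozygous loss (total 0); LOH (minor 0, total ≥ 1 — copy-neutral LOH and
hemizygous loss alike); trisomy-like gain (total 3–4, both alleles
retained); amplification (total ≥ 5); neutral (2/1). Published category
names come without cutoffs, so these integer thresholds follow common
practice and are configuration.

LOH% is 100 × (union length of LOH segments) / (genome length from the
chromosome table). A ratio of LOH segment count to total CNV count cannot
reproduce published LOH percentages (e.g. 170 LOH among 247 CNVs printed
as 53.6%), so the genome-fraction definition is adopted and documented.

The HRD-LOH score counts LOH segments strictly longer than 15 Mb and
strictly shorter than their chromosome, following the genomic-scar
literature; `hrd_high` at score ≥ 10. Telomeric allelic imbalance and
large-scale transitions are out of scope.

## Cohort statistics

Incidence percents round half-up on the percent scale — the only rounding
consistent with displayed pairs like 6/7→86, 4/7→57, 3/7→43. Recurrence
keeps genes in strictly more than 2 cases. Over-representation compares
the *rounded* cohort percent against the reference percent with strict
inequality at fold 2 — verified to be the only convention reproducing the
published 8-gene list (43 vs 40 excluded, 43 vs 7 included). Promoter
mutations count toward gene incidence like coding ones. Reference
percentages are consumed as a table, never recomputed, and no significance
test is attached — the published comparison is a fold filter.

## Synthetic data: what it emulates, what it does not

Generators are seeded (`numpy` PCG64; per-case child seeds at a fixed
prime stride) and their defaults state the world once:

* signature matrices: symmetric Dirichlet over 96 channels, concentration
  0.1 — spiky, well-separated profiles like real SBS signatures;
* catalogs: multinomial draws from `Σ_k π_k s_k·` — exactly the model the
  EM inverts, so recovery tests are calibration tests;
* cohorts: 7 cases by default (the reference cohort size); true categories
  from a (0.5, 0.3, 0.2) clonal/polyclonal/subclonal mix; clonal true VAF
  fixed at 0.50 (the heterozygous purity-1 arithmetic), polyclonal uniform
  on [0.20, 0.45], subclonal on [0.01, 0.0999]; observed VAF binomial at
  depth 60 (typical tumor WGS coverage), `depth=None` for noise-free mode;
* segments: prescribed classes packed without overlap on a toy genome,
  remainder neutral diploid.

Because clonal truth sits exactly on the 0.50 band edge and poly/subclonal
truths run to their band edges, binomial noise at any finite depth sends
edge draws into the adjacent indeterminate gap at ~50% odds. Truth
recovery is therefore asserted as: > 95% per open band, misses only in the
adjacent gap, clonal calls only clonal-or-indeterminate — not a blanket
> 99%. A green synthetic test establishes internal consistency of model
and inference, not robustness to what real data adds: purity < 1,
copy-number-distorted VAFs, caller artifacts, mutation clustering along
the genome and realistic coordinates are all absent by design.

## Numerical choices and degenerate inputs

Signature rows off 1 by ≤ 1e-4 are renormalized, further off is fatal
naming the offender; exposures validate to Σπ = 1 within 1e-9. An empty
catalog or an observed channel unreachable by every signature is a fatal
error (likelihood undefined). K = 1 returns π = (1.0) in one iteration.
EM monotonicity is asserted to −1e-9 to absorb float rounding. Pruning
that would remove every signature keeps the largest. The per-case report
is deterministic given inputs and config (byte-identical JSON, sorted
keys), and its layout is published as `src/twm/data/case_report.schema.json`.

## Known limitations

No purity/ploidy-aware cancer-cell-fraction model; no doublet or indel
catalogs; no de novo signature extraction; no multiple-testing machinery
(nothing here tests hypotheses); bundled reference tables are summary-level
only — per-case variant lists are not redistributed; the published
per-case WGS-TMB values are approximated (3% band), not reproduced exactly,
for the callable-size reason above.
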