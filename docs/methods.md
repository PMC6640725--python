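# Methods

## Scope and model

The package re-implements a two-part data-mining analysis of how a
stimulus (low-intensity ultrasound and its surrogate conditions — mild
hyperthermia, oscillatory shear stress, transcription-factor
perturbations) shifts the expression of a curated *cell-death
regulatome*: 299 genes regulating 13 cell-death modalities. Part one is
a screening layer — signed fold-change classification at a fixed
threshold, housekeeping-gene quality control, per-modality annotation,
and cross-condition overlap. Part two is a chromatin long-range
interaction (CLRI) layer — promoter-anchored signed distances between a
gene and its chromatin interaction partners, distribution summaries,
and a two-sample Kolmogorov–Smirnov comparison of two gene sets'
distance distributions.

## The packaged regulatome

The registry transcribes the curated per-modality gene lists verbatim
(including case as printed) and normalizes symbols by stripping and
upper-casing only. Within a modality, duplicated symbols are collapsed
(one list prints `ROS1` twice; its printed gene number counts unique
symbols). Rodent-cased symbols (`Nlrp1b`, `Naip5`, `Serpina3g`) are
upper-cased but not mapped to human orthologs: the curation pools
species, and downstream overlaps are likewise computed on normalized
symbols without ortholog resolution.

Counting conventions. The packaged lists give 390 type memberships over
299 distinct symbols. The registry reports `multi_type_genes` as the
membership excess (390 − 299 = 91), because that is the arithmetic the
curation reconciles to; the literal number of genes appearing under two
or more modalities is 67 (18 genes span three to five modalities, e.g.
TP53 under apoptosis, MPT-driven necrosis, ferroptosis,
autophagy-dependent and mitotic death) and is exposed separately as
`genes_in_multiple_types`. The two figures coincide only when no gene
spans three or more modalities, which is not the case here; both are
therefore reported rather than silently conflated.

Two symbol ambiguities are left unresolved by design. The necroptosis
list prints `FASG`, plausibly a typo for `FASLG`; mapping it would
change the totals (298 unique / 92 excess), so it is retained verbatim
and the alias table ships empty. `ANAX1` appears once in narrative text
where the tables print `ANXA1`; no packaged input uses the variant, so
no alias entry is shipped. The alias mechanism itself is fully
functional (TSV of `raw → canonical` with a documented reason per
entry, validated to be a forest into canonical symbols and to be
exercised by the packaged lists).

## Fold-change convention and classifier

Signed fold changes use the reciprocal-negative convention: a
treated/control ratio r ≥ 1 encodes as +r, a ratio r < 1 as −1/r, so
values never fall in the open interval (−1, 1) and a ratio of exactly 1
encodes as +1.0 (not −1.0; canonical form must be unique). Encoding and
decoding round-trip to 1e−12 relative tolerance.

The classifier calls a gene *up* when its signed fold change strictly
exceeds the threshold (default 1.5) and *down* when strictly below the
negated threshold — strict because the rule is "more than" a 1.5-fold
change; no packaged value sits exactly at the cut, so strictness does
not alter any packaged result. Universe genes absent from a dataset are
reported as *not measured*, never as unchanged: platform and species
differences make absence routine and conflating it with stability would
bias overlap counts. Panel screens (redox enzymes,
chromatin-conformation factors) are the one exception: their source
tables print only above-threshold values, so a panel gene missing from
a screen table is unchanged-below-threshold by convention
(`absent_as_unchanged=True`).

Housekeeping QC collects the fold changes of CHMP2A, PSMB4, ACTB and
GAPDH across all datasets and passes when every available value has
magnitude strictly below the threshold (default 1.5, the same magnitude
as the differential cut; the packaged values span [−1.271, 1.284] and
pass). Missing cells are counted, not imputed — one packaged series
lacks its CHMP2A probe.

No p-value enters the classification: the screening rule is
fold-change-only, and the ingest layer carries optional p-values purely
as annotation.

## CLRI distance analysis

Coordinate conventions. Interaction text dumps are assumed 1-based
inclusive (the common dialect for such exports) and converted to
0-based half-open internally; a dialect flag switches this off for
already half-open input. Promoter tables are BED6 (anchored at `start`)
or two-column `gene/tss` with an explicit chromosome.

For a target gene, the signed distance to an interaction partner is
`partner_anchor − target_promoter_tss` in pure genomic orientation:
positive means the partner lies downstream (higher coordinate).
Strand is ignored for the sign by default — distances are differences
between gene start coordinates in genomic terms — with a
`strand_aware` mode (sign flipped for minus-strand targets) available
behind a flag. The partner anchor prefers the annotated gene start of
the first listed partner gene that has a promoter entry on the same
chromosome; unannotated anchors fall back to the interval midpoint
(floor). Trans records (different chromosomes) and records carrying the
target on both sides are excluded with explicit counts, never silently
dropped, so distance counts are conserved end to end. A zero distance
is retained (counted as downstream) and flagged in diagnostics.
Duplicate interaction rows are retained by default — database dumps
contain method/cell-type replicates — with `dedupe` available.

Distribution summaries report the upstream and downstream fractions and
a signed log-magnitude histogram with decade edges at 10^k bp,
k = 3…8, mirrored about zero; |d| < 10^3 pools into the central bin
and |d| ≥ 10^8 into the outermost bins, so counts always sum to the
sample size.

Kolmogorov–Smirnov comparison. D is the supremum of |ECDF₁ − ECDF₂|
over the pooled sample points (verified in tests against a brute-force
oracle and against an independent library implementation). The
asymptotic p evaluates the Kolmogorov distribution at the classical
Smirnov argument λ = √(n₁n₂/(n₁+n₂))·D. The familiar
(√nₑ + 0.12 + 0.11/√nₑ) inflation of λ was considered and rejected: it
is a one-sample-test correction, and against exact permutation p-values
at n₁ = n₂ = 7 it overstates significance by up to 0.15, whereas the
plain argument agrees with the exact p within 0.034 across 200 random
null samples. For pooled sizes ≤ 14 an exact p is computed by full
enumeration of the C(n₁+n₂, n₁) equally likely assignments of the
pooled values (counting splits with D ≥ observed, tolerance 1e−12 for
ties); this matches the reference exact implementation bit-for-bit. p
is capped at 1 and the test is two-sided only.

## Synthetic data

The expression generator emulates two-condition, replicated,
intensity-scale microarray data: control intensities are
`baseline · 2^N(0, noise_sd)` and treated samples additionally carry
planted multiplicative effects (≥ 1, direction recorded in a truth
table). Noise is multiplicative log-normal, not additive, so
fold-change semantics are exact in the noiseless limit. Defaults —
200 genes, 3+3 replicates, baseline 100, log2-scale noise sd 0.1,
planted effects 2.0 — reflect a small two-group array comparison with
moderate technical noise and effects comfortably above the 1.5-fold
cut. The generator does not simulate probe-level artifacts, batch
effects, inter-gene correlation or platform-specific missingness, so
recovery results bound performance under idealized noise only.

The interaction generator lays genes on synthetic chromosomes (50 genes
per chromosome, TSSs 2×10^8 bp apart, so magnitudes ≤ 10^8 bp can never
be attributed to the wrong gene) and places each partner site
downstream with probability β at a log-uniform magnitude in
[10^4, 10^8] bp, the span over which real interaction sites concentrate;
partner intervals are centered on the drawn point so midpoint anchoring
recovers the magnitude exactly. Trans rows pointing at a decoy
chromosome are injected with probability `trans_prob`. It does not
emulate contact-frequency decay with distance, anchor-size variation or
shared partners between genes. All generators are pure functions of
their spec including the seed.

The headline chromatin result of the source analysis (a p < 0.001
comparison over 555 database-extracted interaction sites) depends on a
specific database version and gene annotation that are not
redistributable; it is therefore covered by property-based substitutes
(oracle-checked D, exact-vs-asymptotic agreement, count conservation,
and KS power ≥ 95% at α = 0.001 for β = 0.5 vs 0.8 with 500
interactions per set over 200 seeded replicates) rather than by a
numeric reproduction.

## Problem sizes and determinism

All screening reproductions run on the packaged desk-scale fixtures
(25–42 measured genes per condition) in well under a second. The KS
power check uses 200 replicates of 500 distances per arm and the
recovery check 200 genes at 3+3 replicates; both complete in seconds.
Classification, registry loading and fixture ingest are fully
deterministic; every stochastic component takes an explicit seed.

## Known limitations

- Cross-species overlaps are symbol-level; orthologs with diverged
  names will not match.
- The naive two-group fold change (`compute_differential`) is a plain
  group-mean ratio without moderated variance estimation; it stands in
  for upstream differential-expression tooling, not for a statistical
  test.
- The overlap layer reports set intersections only; no enrichment
  statistic is attached to an overlap.
- The exact KS p is limited to pooled sizes ≤ 14 by combinatorial
  enumeration; larger samples rely on the asymptotic p.
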