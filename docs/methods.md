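# Methods

This note documents the models, conventions and numerical choices behind
`tibrep`, and what the synthetic-data generator does and does not emulate.

## Clone-table ingestion and QC

Clonotype tables are consumed in two dialects (AIRR Rearrangement TSV, MiXCR
clone export); V(D)J alignment itself is out of scope. Retention follows the
two thresholds standard for BCR mining from bulk RNA-seq: a sample enters
cohort statistics only with at least **500 reads mapped to the Ig loci**
(`min_ig_reads`), and clonotypes need at least **3 supporting reads**
(`min_clone_count`). The Ig-mapped read count normally comes from the
aligner's report; when no sidecar read-depth table is supplied it defaults to
the clone-count sum, which counts clone-supporting reads only — callers who
care about the distinction should provide the sidecar. Failing samples are
flagged (`qc_pass=False`) rather than discarded so paired tumor/normal
bookkeeping survives. Gene calls are resolved by stripping IMGT allele
suffixes (`*01`) before uniqueness testing; a call list with two or more
distinct genes is AMBIGUOUS at gene level but may still resolve at subgroup
(family-prefix) level. CDR3 identity is case-insensitive; sequences are
upper-cased on ingest, and records whose amino-acid CDR3 disagrees with the
frame-0 translation of the nucleotide CDR3 are flagged, not dropped.

## Repertoire statistics

All fractions are clone-count weighted. Usage tables and the V-subgroup ×
J-gene rearrangement matrix exclude clones with ambiguous calls from both
numerator and denominator, so every table sums to 1 over what it retains.
Clonality is `1 − H/ln S` with natural-log Shannon entropy `H` over the `S`
retained clonotypes; the log base cancels in the ratio. A single-clone
repertoire is defined as clonality 1 (the oligoclonal limit; avoids 0/0).
Sharing and the Jaccard index default to amino-acid CDR3 keys and are
unweighted presence/absence; both set sizes and the fraction-of-union are
reported so alternative shared-fraction denominators can be recovered.
Isotype class tallies are permissive (any IgG-subclass call counts toward
IGHG) while subclass tallies are strict (exactly one resolved subclass);
CPM = clonotypes × 10⁶ / total sequencing reads and is unavailable (never
silently wrong) when total depth is unknown.

## SHM lineages

The mutation primitive is **one base mismatch or one single-base
deletion** between CDR3 nucleotide sequences. Insertions are accepted too
(flag `allow_indel`, default on): a deletion in one sequence is an insertion
in the other, so excluding them would make linking asymmetric. Linking
requires a shared resolved V and J gene — cross-V linking would conflate
convergent CDR3s from unrelated rearrangements; this is the major
interpretive choice in the module. Duplicate rows with identical
(V, J, CDR3nt) — e.g. class-switch duplicates — are merged into one
clonotype node before linking. Connected components of the 1-edit graph are
lineages; in principle a chain can place a member at edit distance 2 from
the root, and components (not stars) are what the brute-force oracle checks.
The root is the maximal-count member, ties broken toward the
lexicographically smallest CDR3 for deterministic output. The mutation ratio
counts clonotypes, not reads (a read-weighted variant is exposed); variants
are classed synonymous/nonsynonymous by frame-0 translation, indel when
lengths differ, and out-of-frame substitutions are classed nonsynonymous
with a warning since the protein-level comparison is undefined.

## CSR co-occurrence

A clonotype observed in exactly two constant-region subclasses — either one
row with a two-subclass call or merged rows with different single
subclasses — adds one count to that unordered pair's edge. Clones with one
or ≥ 3 subclasses contribute nothing. Pair shares are reported over all
co-occurring clonotypes; per-subclass co-occurrence totals are also exposed
because the alternative denominator (all co-occurring clones of one
subclass) is equally defensible.

## Survival stratification

Markers are computed on the FPKM scale; log2(FPKM+1) input is
back-transformed first. Ratio markers use a denominator pseudocount of
0.01 FPKM (configurable) to handle zero MS4A1. The IGH sum covers IGHG1-4,
IGHA1-2, IGHD and IGHM; the IGHG sum covers IGHG1-4.

The cutpoint is the maximally selected rank statistic: among splits at
observed marker values leaving both groups ≥ max(0.15 · n, 20) patients, the
one maximizing |Z| of the standardized log-rank statistic
(Z = (O−E)/√V with the hypergeometric variance) is chosen; ties break toward
the smaller cutpoint and the returned value is the midpoint between the
boundary observations. The reported log-rank p at the selected cutpoint is
the plain, uncorrected test and is therefore **anti-conservative**; the
model emits a standing warning instead of applying a selection correction
(corrected maximally-selected p-values are deliberately out of scope).

Cox models use lifelines with Efron tie handling. Age enters continuous,
stage as ordinal 1-4 (roman numerals are encoded), binaries as 0/1;
complete-case analysis with a logged exclusion count. The multivariable
model uses the marker dichotomized at the same full-cohort cutpoint as the
KM plot by default; a continuous standardized-marker form is exposed.
Subtype-combined analysis dichotomizes once on the full cohort, then reports
KM/log-rank and Cox within each molecular subtype and pooled over
non-stemness subtypes; subtypes too small or degenerate to fit are skipped
with a recorded reason.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
study-realistic settings:

* **V/J usage**: multinomial over a 17-gene IGHV panel whose top five
  weights (IGHV3-23 10.7%, IGHV1-18 7.7%, IGHV4-39 7.6%, IGHV3-21 6.1%,
  IGHV5-51 4.9%) follow the usage skew reported for esophageal tumors, and a
  J panel dominated by IGHJ4/IGHJ6.
* **Expansion**: clone counts are 2 + Zipf(exponent) truncated at 10⁴. The
  offset keeps every emitted clone above the 3-read retention threshold so
  planted structure survives QC; the power law is the standard oligoclonal
  assumption. Tumor samples use a sharper exponent (2.2) than normals (3.5),
  making tumors more oligoclonal.
* **CDR3s**: random in-frame codon strings with Cys…Trp anchors, lengths
  9-24 aa around a 15-17 mode. No junction biology (no germline V/D/J
  segments, no sequencing error) is modeled.
* **SHM**: each base clone emits one 1-edit variant with probability
  `shm_prob` (default 0.05; 80% substitutions, 20% single-base deletions),
  with a smaller count. Because the mutation-ratio denominator includes the
  variants, the planted probability is re-estimated as r/(1−r) from the
  measured ratio r. Substitutions are uniform, so the generator does *not*
  reproduce the synonymous excess seen in real repertoires.
* **CSR**: with the per-pair probabilities (default total rate 5%, IgG2/4
  leading at 40% of events) a clone is emitted as two rows with different
  single subclasses, exercising the merge rule.
* **Cohort**: subtype mixture over
  differentiated/immunogenic/metabolic/stemness; log-normal expression
  around subtype-specific means (immunogenic Ig/MS4A1-high, stemness
  B-cell-poor, housekeeping decoys flat); exponential survival in months
  with hazard `h₀·exp(β_marker·1[ratio>median] + βᵀ·covariates)`, optional
  restriction of the marker effect to chosen subtypes, independent
  exponential censoring plus a 60-month administrative cutoff; a small
  planted tumor/normal clone overlap (1%) yields paired Jaccard indices of
  the right order (~0.005). The planted marker effect is binary at the
  realized cohort median because the dichotomizing pipeline is the estimator
  being validated; a linear (standardized log-ratio) form is available.

Passing tests on these data certify the pipeline's arithmetic and its
parameter recovery under the generative assumptions; they do not certify
robustness to aligner artefacts, sequencing error, germline polymorphism or
non-exponential survival, none of which are emulated.

## Problem sizes and tolerances

Oracle-equivalence tests use 20 random repertoires of ≤ 300 base clones
(SHM lineages vs an O(n²) edit-distance oracle) and 30 survival datasets of
n = 60 (cutpoint vs exhaustive search). Distribution recovery uses 10⁵
clones for usage (total-variation < 0.02), 5·10³ for SHM (3 binomial SEs)
and ~10⁴ co-occurring clonotypes for CSR shares (3 multinomial SEs).
End-to-end hazard recovery uses n = 500 cohorts, 10 seeds per planted effect,
requiring the estimate within 2 SE in ≥ 8/10 seeds. Under a planted null the
dichotomized estimate at a maximally selected cutpoint is inflated by
selection (its magnitude is roughly the supremum of the standardized
log-rank process over admissible splits, ≈ 2.2 SE for minimum proportion
0.15), so nominal 2-SE coverage is not achievable there by construction —
this is the same anti-conservatism the standing warning documents, and the
null-recovery check records it rather than correcting for it. Fraction
tables are asserted to 1e-9; Cox coefficients are cross-checked against an
independent partial-likelihood implementation to 1e-4 relative.

## Known limitations

Light-chain pairing, germline-alignment-based SHM across the V region,
phylogenetic lineage trees, repertoire-overlap significance beyond Jaccard,
proportional-hazards diagnostics, competing risks and multiplicity
correction across markers are all out of scope. The "infiltration"
covariate is treated as an opaque numeric column.
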