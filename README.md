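# tibrep

Intra-tumoral B-cell immunoglobulin repertoire analysis from bulk RNA-seq
clonotype tables, with prognostic stratification of plasma-cell biomarkers.

## What problem this addresses

Bulk RNA-seq of solid tumors captures enough immunoglobulin transcripts to
reconstruct the infiltrating B-cell receptor (BCR) repertoire: V(D)J aligners
such as MiXCR emit per-sample clonotype tables (CDR3 sequence, V/J/constant
gene calls, supporting read counts). `tibrep` takes those tables — together
with per-sample read depths, a gene-expression matrix and patient survival
metadata — and computes the repertoire and survival statistics used to
characterize tumor-infiltrating B cells (TIBs) and their prognostic value:

* **QC / retention**: samples with ≥ 500 Ig-mapped reads; clonotypes with
  ≥ 3 supporting reads (both configurable).
* **Repertoire statistics**: total abundance N = Σ clone counts; V/J usage
  fractions over unambiguously mapped genes; the V-subgroup × J-gene
  rearrangement matrix; CDR3 length spectra; clone sharing and the Jaccard
  index between paired tumor/normal samples; isotype/subclass tallies with
  clonotypes-per-million (CPM = clonotypes × 10⁶ / total reads).
* **Clonality**: `1 − H/ln S` where `H = −Σ pᵢ ln pᵢ` is the Shannon-Wiener
  index of clone frequencies (0 = evenly distributed/diverse,
  1 = monoclonal).
* **Somatic hypermutation (SHM)**: clonotypes sharing a resolved V and J and
  differing by exactly one base (mismatch or single-base indel) are linked
  into lineages; the mutation ratio is the fraction of clonotypes that are
  non-root lineage members, with variants classed
  synonymous / nonsynonymous / indel.
* **Class-switch recombination (CSR)**: a clonotype observed under two
  constant-region subclasses contributes one count to that subclass pair's
  co-occurrence edge; pair shares are reported over all co-occurring clones.
* **Survival stratification**: expression biomarkers (the IGH FPKM sum over
  IGHG1-4/IGHA1-2/IGHD/IGHM, the IGHG sum, and plasma-cell ratios such as
  IGHG2:MS4A1) are dichotomized at the maximally selected log-rank cutpoint
  (minimum group proportion 0.15, minimum 20 patients per group) and tested
  with Kaplan-Meier / log-rank plus multivariable Cox regression (Efron
  ties), adjusted for gender, age, smoking, drinking, stage and
  infiltration — optionally within molecular subtypes and pooled over
  non-stemness subtypes.

A first-class synthetic-data module generates clone tables, expression and
survival metadata with planted structure (usage weights, SHM rate, CSR pair
probabilities, a marker hazard ratio), so the whole pipeline is testable
end-to-end with no sequencing download.

## Worked example

```python
import numpy as np
from tibrep import (CohortSimConfig, GeneRatio, MarkerStratification,
                    compute_biomarker, simulate_cohort, clonality)

sim = simulate_cohort(CohortSimConfig(n_patients=200, seed=1))

# repertoire side: tumors are more oligoclonal than matched normals
t = np.median([clonality(r) for r in sim.repertoires.values() if r.tissue == "tumor"])
n = np.median([clonality(r) for r in sim.repertoires.values() if r.tissue == "normal"])
print(f"median clonality tumor {t:.4f} vs normal {n:.4f}")

# survival side: stratify the IgG2 plasma-cell ratio
marker = compute_biomarker(sim.tables, GeneRatio(("IGHG2",), "MS4A1",
                                                 name="IGHG2_MS4A1_ratio"))
covs = ("gender", "age", "smoking", "drinking", "stage", "infiltration")
res = MarkerStratification.from_cohort(sim.tables, marker, covs).fit()
print(res.summary())
```

prints (elided):

```
median clonality tumor 0.0673 vs normal 0.0029
Marker stratification: IGHG2_MS4A1_ratio
  n = 200 (low 100 / high 100), cutpoint = 6.22543 [selected]
  log-rank chi2 = 15.39, p = 8.722e-05
  Cox proportional hazards (Efron ties):
    covariate                   HR              95% CI         p
    ...
    IGHG2_MS4A1_ratio_high   0.434      [0.271, 0.695]  0.000501
  warning: log-rank p at a selected cutpoint is anti-conservative ...
```

The marker-high group's hazard ratio of 0.43 recovers the protective effect
planted by the simulator (HR 0.4); the warning flags that the log-rank p at a
*selected* cutpoint is optimistic, which the pipeline reports rather than
corrects.

The same analyses run from the shell:

```bash
tibrep simulate --config config.yaml --outdir run     # writes run/data + derived config
tibrep all --config run/pipeline_config.yaml --outdir run/results
```

producing tidy TSV/JSON outputs (QC report, usage tables, lineages, CSR
edges, KM curves, Cox tables) plus a manifest per stage; identical
config + seed reruns are byte-identical.

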