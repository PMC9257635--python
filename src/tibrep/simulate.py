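"""Synthetic clone tables, expression matrices and survival metadata.

The generator emits data with the statistical structure the analysis pipeline
assumes, so every stage is testable without any sequencing download:

* biased V/J-gene usage (multinomial draws; default weights follow the usage
  skew reported for esophageal tumor repertoires, IGHV3-23 at ~10.7% etc.);
* oligoclonal expansion via truncated discrete power-law (Zipf) clone counts;
* random in-frame CDR3 nucleotide sequences with the canonical Cys...Trp
  anchors (no V(D)J junction biology is modeled);
* somatic-hypermutation variants emitted as 1-edit copies of their root clone
  with smaller counts, recorded in a ground-truth ledger;
* class-switch clonotypes emitted as duplicate rows carrying two different
  constant-region subclasses;
* a patient cohort with subtype-dependent immunoglobulin expression, an
  IGHG2:MS4A1 ratio marker with a planted hazard effect, exponential survival
  and independent censoring, and paired tumor/normal repertoires with the
  tumor made more oligoclonal via a sharper expansion exponent.

All randomness flows from a single integer seed; identical configs and seeds
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.Data.CodonTable import standard_dna_table

from .clone_io import CloneRecord, CohortTables, Repertoire, write_clone_table
from .exceptions import ConfigError

#: Sense codons (no stops), fixed order for reproducibility.
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
_CYS, _TRP = "TGT", "TGG"


def _normalized(weights: Mapping, total: float = 1.0) -> dict:
    s = float(sum(weights.values()))
    return {k: v * total / s for k, v in weights.items()}


# Tumor-side heavy-chain V usage: the five most-used genes carry the fractions
# reported for ESCC tumors; the remainder spreads over common IGHV genes.
DEFAULT_V_USAGE = _normalized({
    "IGHV3-23": 0.1071, "IGHV1-18": 0.0773, "IGHV4-39": 0.0764,
    "IGHV3-21": 0.0614, "IGHV5-51": 0.0492,
    "IGHV3-74": 0.040, "IGHV3-30": 0.080, "IGHV1-2": 0.070,
    "IGHV4-59": 0.065, "IGHV3-7": 0.060, "IGHV3-48": 0.060,
    "IGHV4-34": 0.055, "IGHV1-69": 0.050, "IGHV2-5": 0.040,
    "IGHV6-1": 0.030, "IGHV7-4-1": 0.020, "IGHV3-15": 0.058,
})
DEFAULT_J_USAGE = _normalized({
    "IGHJ4": 0.38, "IGHJ6": 0.24, "IGHJ5": 0.12, "IGHJ3": 0.11,
    "IGHJ2": 0.08, "IGHJ1": 0.07,
})
#: CDR3 amino-acid lengths, triangular around the 15-17 aa mode.
DEFAULT_CDR3_LENGTHS = _normalized(
    {L: float(min(L - 8, 25 - L)) for L in range(9, 25)}
)
DEFAULT_ISOTYPES = _normalized({
    "IGHG1": 0.30, "IGHG2": 0.12, "IGHG3": 0.08, "IGHG4": 0.04,
    "IGHA1": 0.18, "IGHA2": 0.07, "IGHM": 0.15, "IGHD": 0.05, "IGHE": 0.01,
})
#: Absolute per-clone co-occurrence probabilities (sum = overall CSR rate).
#: Pair shares follow the reported ranking (IgG2/4 first, IgG3/1 second).
DEFAULT_CSR_PAIRS = _normalized({
    ("IGHG2", "IGHG4"): 0.40, ("IGHG1", "IGHG2"): 0.18, ("IGHG1", "IGHG3"): 0.16,
    ("IGHA1", "IGHA2"): 0.14, ("IGHG1", "IGHG4"): 0.12,
}, total=0.05)


@dataclass
class RepertoireSimConfig:
    """Generative settings for one sample's clone table.

    ``expansion`` is the power-law exponent of the clone-count distribution
    (larger = flatter = more diverse); counts are ``count_offset + Zipf`` so
    every emitted clone clears the 3-read retention threshold. ``shm_prob``
    is the per-clone probability of emitting one 1-edit variant clone;
    ``csr_pair_probs`` map subclass pairs to absolute per-clone co-occurrence
    probabilities (their sum is the overall CSR rate, <= 1).
    """

    n_clones: int = 1000
    v_usage_weights: dict = field(default_factory=lambda: dict(DEFAULT_V_USAGE))
    j_usage_weights: dict = field(default_factory=lambda: dict(DEFAULT_J_USAGE))
    expansion: float = 2.5
    count_offset: int = 2
    count_max: int = 10_000
    shm_prob: float = 0.05
    shm_indel_prob: float = 0.2
    csr_pair_probs: dict = field(default_factory=lambda: dict(DEFAULT_CSR_PAIRS))
    isotype_probs: dict = field(default_factory=lambda: dict(DEFAULT_ISOTYPES))
    cdr3_length_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_CDR3_LENGTHS)
    )
    total_reads: int = 50_000_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("v_usage_weights", "j_usage_weights", "isotype_probs",
                     "cdr3_length_distribution"):
            mapping = getattr(self, name)
            if not mapping:
                raise ConfigError(f"{name} is empty")
            total = sum(mapping.values())
            if any(v < 0 for v in mapping.values()) or abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        csr_total = sum(self.csr_pair_probs.values())
        if any(v < 0 for v in self.csr_pair_probs.values()) or csr_total > 1.0 + 1e-9:
            raise ConfigError("csr_pair_probs must be non-negative with sum <= 1")
        if not 0.0 <= self.shm_prob <= 1.0:
            raise ConfigError("shm_prob must lie in [0, 1]")
        if self.expansion <= 1.0:
            raise ConfigError("expansion exponent must exceed 1")
        if self.n_clones < 1 or self.count_max < 1 or self.total_reads < 1:
            raise ConfigError("n_clones, count_max and total_reads must be positive")


def _random_cdr3(rng: np.random.Generator, aa_len: int) -> str:
    middle = rng.integers(0, len(SENSE_CODONS), size=aa_len - 2)
    return _CYS + "".join(SENSE_CODONS[i] for i in middle) + _TRP


def _mutate(rng: np.random.Generator, cdr3: str, indel_prob: float) -> str:
    """One random edit: a substitution, or (with indel_prob) a deletion."""
    if rng.random() < indel_prob and len(cdr3) > 3:
        pos = int(rng.integers(0, len(cdr3)))
        return cdr3[:pos] + cdr3[pos + 1:]
    pos = int(rng.integers(0, len(cdr3)))
    alternatives = [b for b in "ACGT" if b != cdr3[pos]]
    base = alternatives[int(rng.integers(0, 3))]
    return cdr3[:pos] + base + cdr3[pos + 1:]


def simulate_repertoire(
    config: RepertoireSimConfig,
    sample_id: str = "sim",
    patient_id: str = "",
    tissue: str = "tumor",
    rng: np.random.Generator | None = None,
) -> tuple[Repertoire, dict]:
    """Draw one repertoire plus its ground-truth ledger.

    The ledger records the planted V/J weights, every emitted SHM
    root/variant pair and every CSR clonotype with its subclass pair, so
    recovery tests can compare measured statistics against the truth.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    v_names = sorted(config.v_usage_weights)
    v_p = np.array([config.v_usage_weights[g] for g in v_names])
    j_names = sorted(config.j_usage_weights)
    j_p = np.array([config.j_usage_weights[g] for g in j_names])
    lengths = sorted(config.cdr3_length_distribution)
    len_p = np.array([config.cdr3_length_distribution[L] for L in lengths])
    iso_names = sorted(config.isotype_probs)
    iso_p = np.array([config.isotype_probs[s] for s in iso_names])
    csr_pairs = sorted(config.csr_pair_probs)
    csr_p = np.array([config.csr_pair_probs[p] for p in csr_pairs])
    k = np.arange(1, config.count_max + 1, dtype=float)
    count_pmf = k ** -config.expansion
    count_pmf /= count_pmf.sum()

    n = config.n_clones
    v_idx = rng.choice(len(v_names), size=n, p=v_p)
    j_idx = rng.choice(len(j_names), size=n, p=j_p)
    len_idx = rng.choice(len(lengths), size=n, p=len_p)
    counts = config.count_offset + rng.choice(
        np.arange(1, config.count_max + 1), size=n, p=count_pmf
    )
    iso_idx = rng.choice(len(iso_names), size=n, p=iso_p)
    csr_u = rng.random(n)
    shm_u = rng.random(n)
    csr_cum = np.cumsum(csr_p)

    seen: set[str] = set()
    clones: list[CloneRecord] = []
    shm_ledger: list[list[str]] = []
    csr_ledger: list[list[str]] = []

    def record(cdr3: str, v: str, j: str, subclass: str, count: int) -> CloneRecord:
        return CloneRecord(
            cdr3_nt=cdr3,
            cdr3_aa=str(Seq(cdr3[: 3 * (len(cdr3) // 3)]).translate()),
            v_call=(f"{v}*01",),
            j_call=(f"{j}*01",),
            c_call=(subclass,),
            clone_count=int(count),
            sample_id=sample_id,
        )

    for i in range(n):
        aa_len = lengths[len_idx[i]]
        cdr3 = _random_cdr3(rng, aa_len)
        while cdr3 in seen:
            cdr3 = _random_cdr3(rng, aa_len)
        seen.add(cdr3)
        v, j = v_names[v_idx[i]], j_names[j_idx[i]]
        count = int(counts[i])
        pair_pos = int(np.searchsorted(csr_cum, csr_u[i], side="right"))
        if pair_pos < len(csr_pairs):
            a, b = csr_pairs[pair_pos]
            clones.append(record(cdr3, v, j, a, count))
            clones.append(record(cdr3, v, j, b, count))
            csr_ledger.append([cdr3, a, b])
            subclass = a
        else:
            subclass = iso_names[iso_idx[i]]
            clones.append(record(cdr3, v, j, subclass, count))
        if shm_u[i] < config.shm_prob:
            variant = _mutate(rng, cdr3, config.shm_indel_prob)
            while variant in seen:
                variant = _mutate(rng, cdr3, config.shm_indel_prob)
            seen.add(variant)
            vcount = min(count, max(3, int(count * rng.uniform(0.15, 0.8))))
            clones.append(record(variant, v, j, subclass, vcount))
            shm_ledger.append([cdr3, variant])

    rep = Repertoire(
        sample_id=sample_id,
        patient_id=patient_id,
        tissue=tissue,
        clones=clones,
        total_reads=config.total_reads,
        qc_pass=True,
    )
    ledger = {
        "sample_id": sample_id,
        "n_base_clones": n,
        "planted_v_usage": {g: float(p) for g, p in zip(v_names, v_p)},
        "planted_j_usage": {g: float(p) for g, p in zip(j_names, j_p)},
        "shm_prob": config.shm_prob,
        "shm_pairs": shm_ledger,
        "csr_rate": float(csr_p.sum()),
        "csr_pair_probs": {"|".join(p): float(q) for p, q in zip(csr_pairs, csr_p)},
        "csr_clones": csr_ledger,
    }
    return rep, ledger


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

SUBTYPES = ("differentiated", "immunogenic", "metabolic", "stemness")

# log2 expression means per subtype (differentiated, immunogenic, metabolic,
# stemness). Immunoglobulins and MS4A1 peak in the immunogenic subtype;
# stemness is B-cell poor; SDC1 (CD138, plasma cells) is flatter; decoy
# housekeeping genes are subtype-independent.
SUBTYPE_LOG2_MEANS = {
    "IGHG1": (8.0, 10.0, 8.0, 5.0),
    "IGHG2": (7.0, 8.5, 7.0, 4.5),
    "IGHG3": (6.0, 8.0, 6.0, 4.0),
    "IGHG4": (4.0, 5.0, 4.0, 2.0),
    "IGHA1": (7.0, 8.0, 7.0, 5.0),
    "IGHA2": (5.0, 6.0, 5.0, 3.5),
    "IGHD": (2.0, 3.0, 2.0, 1.0),
    "IGHM": (6.0, 8.0, 6.0, 4.0),
    "IGHE": (0.5, 1.0, 0.5, 0.3),
    "MS4A1": (4.0, 7.0, 4.0, 2.5),
    "SDC1": (6.0, 5.0, 6.0, 5.5),
    "ACTB": (11.0, 11.0, 11.0, 11.0),
    "GAPDH": (10.5, 10.5, 10.5, 10.5),
    "TP53": (6.0, 6.0, 6.0, 6.0),
    "KRT5": (9.0, 7.0, 8.0, 7.5),
    "SFRP1": (3.0, 3.0, 3.0, 6.0),
}
#: Relative B-cell infiltration per subtype, scales repertoire size.
SUBTYPE_CLONE_FACTOR = {
    "differentiated": 1.0, "immunogenic": 2.0, "metabolic": 1.0, "stemness": 0.3,
}


@dataclass
class CohortSimConfig:
    """Generative settings for a patient cohort.

    ``marker_log_hr`` is the planted effect of the IGHG2:MS4A1 ratio on the
    hazard. With ``marker_model="threshold"`` the effect is a binary covariate
    switching at the realized cohort median of the ratio (the form the
    dichotomizing pipeline estimates); ``"linear"`` applies it to the
    standardized log ratio instead. Subtypes listed in ``no_effect_subtypes``
    receive no marker effect, so subtype-restricted prognostic structure can
    be planted. Times are in months; survival is
    exponential with an independent exponential + administrative censoring.
    """

    n_patients: int = 119
    subtype_mixture: dict = field(default_factory=lambda: {
        "differentiated": 0.30, "immunogenic": 0.25,
        "metabolic": 0.25, "stemness": 0.20,
    })
    marker_log_hr: float = float(np.log(0.4))
    marker_model: str = "threshold"
    no_effect_subtypes: tuple = ()
    baseline_hazard: float = 0.02        # events per month at covariate means
    censoring_rate: float = 0.012        # independent censoring, per month
    admin_censor_time: float = 60.0      # administrative cutoff (months)
    covariate_log_hrs: dict = field(default_factory=lambda: {
        "gender": 0.10, "age": 0.03, "smoking": 0.20,
        "drinking": 0.10, "stage": 0.35, "infiltration": -0.10,
    })
    expression_sigma: float = 0.6        # log2 sd around subtype means
    with_repertoires: bool = True
    n_clones_tumor: int = 400
    n_clones_normal: int = 400
    tumor_expansion: float = 2.2
    normal_expansion: float = 3.5
    overlap_fraction: float = 0.01       # tumor clones re-observed in normal
    repertoire: RepertoireSimConfig = field(default_factory=RepertoireSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        mix_total = sum(self.subtype_mixture.values())
        if (any(v < 0 for v in self.subtype_mixture.values())
                or abs(mix_total - 1.0) > 1e-9):
            raise ConfigError("subtype_mixture must sum to 1")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.censoring_rate < 0 or self.admin_censor_time <= 0:
            raise ConfigError("censoring settings must be non-negative / positive")
        if self.marker_model not in ("threshold", "linear"):
            raise ConfigError(f"unknown marker_model {self.marker_model!r}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigError("overlap_fraction must lie in [0, 1]")
        if self.tumor_expansion <= 1.0 or self.normal_expansion <= 1.0:
            raise ConfigError("expansion exponents must exceed 1")
        self.repertoire.validate()


@dataclass
class SimulatedCohort:
    tables: CohortTables
    repertoires: dict[str, Repertoire]
    ledger: dict
    config: CohortSimConfig


def simulate_cohort(
    config: CohortSimConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Draw a full cohort: metadata, expression, and paired repertoires."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"P{i + 1:04d}" for i in range(n)]
    subtype_names = sorted(config.subtype_mixture)
    subtype_p = np.array([config.subtype_mixture[s] for s in subtype_names])
    subtypes = [subtype_names[i] for i in rng.choice(len(subtype_names), size=n, p=subtype_p)]

    gender = rng.binomial(1, 0.8, size=n)
    age = np.round(rng.normal(60.0, 8.0, size=n), 1)
    smoking = rng.binomial(1, 0.6, size=n)
    drinking = rng.binomial(1, 0.5, size=n)
    stage = 1 + rng.choice(4, size=n, p=[0.10, 0.35, 0.45, 0.10])
    infiltration = np.round(rng.normal(0.0, 1.0, size=n), 3)

    genes = sorted(SUBTYPE_LOG2_MEANS)
    subtype_pos = {s: i for i, s in enumerate(SUBTYPES)}
    log2 = np.empty((len(genes), n))
    for gi, gene in enumerate(genes):
        means = np.array([
            SUBTYPE_LOG2_MEANS[gene][subtype_pos[s]] for s in subtypes
        ])
        log2[gi] = means + config.expression_sigma * rng.standard_normal(n)
    log2 = np.maximum(log2, 0.0)
    samples = [f"{p}_T" for p in patients]
    expression = pd.DataFrame(np.round(log2, 6), index=genes, columns=samples)
    expression.index.name = "gene"

    fpkm = 2.0 ** log2 - 1.0
    ighg2 = fpkm[genes.index("IGHG2")]
    ms4a1 = fpkm[genes.index("MS4A1")]
    marker = ighg2 / (ms4a1 + 0.01)
    marker_high = marker > np.median(marker)

    beta = config.covariate_log_hrs
    lp = (
        beta.get("gender", 0.0) * (gender - gender.mean())
        + beta.get("age", 0.0) * (age - age.mean())
        + beta.get("smoking", 0.0) * (smoking - smoking.mean())
        + beta.get("drinking", 0.0) * (drinking - drinking.mean())
        + beta.get("stage", 0.0) * (stage - stage.mean())
        + beta.get("infiltration", 0.0) * (infiltration - infiltration.mean())
    )
    affected = np.array([s not in config.no_effect_subtypes for s in subtypes])
    if config.marker_model == "threshold":
        lp = lp + config.marker_log_hr * marker_high.astype(float) * affected
    else:
        logm = np.log(marker + 1e-9)
        lp = lp + (
            config.marker_log_hr * (logm - logm.mean()) / logm.std(ddof=0) * affected
        )
    hazard = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = np.minimum(
            rng.exponential(1.0 / config.censoring_rate, size=n),
            config.admin_censor_time,
        )
    else:
        censor_time = np.full(n, config.admin_censor_time)
    os_time = np.round(np.minimum(event_time, censor_time), 3)
    os_event = (event_time <= censor_time).astype(int)

    metadata = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "gender": gender,
            "age": age,
            "smoking": smoking,
            "drinking": drinking,
            "stage": stage,
            "infiltration": infiltration,
            "subtype": subtypes,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    tables = CohortTables(
        metadata=metadata,
        expression=expression,
        scale_flag="log2fpkm1",
        sample_map={s: p for s, p in zip(samples, patients)},
    )

    repertoires: dict[str, Repertoire] = {}
    rep_ledgers: dict[str, dict] = {}
    if config.with_repertoires:
        for p, subtype in zip(patients, subtypes):
            factor = SUBTYPE_CLONE_FACTOR[subtype]
            tumor_cfg = dataclasses.replace(
                config.repertoire,
                n_clones=max(20, int(config.n_clones_tumor * factor)),
                expansion=config.tumor_expansion,
            )
            normal_cfg = dataclasses.replace(
                config.repertoire,
                n_clones=max(20, config.n_clones_normal),
                expansion=config.normal_expansion,
            )
            for tissue, cfg in (("tumor", tumor_cfg), ("normal", normal_cfg)):
                sid = f"{p}_{'T' if tissue == 'tumor' else 'N'}"
                child = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
                rep, ledger = simulate_repertoire(
                    cfg, sample_id=sid, patient_id=p, tissue=tissue, rng=child,
                )
                repertoires[sid] = rep
                rep_ledgers[sid] = ledger
            if config.overlap_fraction > 0:
                _plant_overlap(rng, repertoires[f"{p}_T"], repertoires[f"{p}_N"],
                               config.overlap_fraction)
    ledger = {
        "marker_log_hr": float(config.marker_log_hr),
        "marker_model": config.marker_model,
        "no_effect_subtypes": list(config.no_effect_subtypes),
        "marker_median": float(np.median(marker)),
        "marker_high": {p: bool(h) for p, h in zip(patients, marker_high)},
        "subtypes": dict(zip(patients, subtypes)),
        "repertoires": rep_ledgers,
    }
    return SimulatedCohort(
        tables=tables, repertoires=repertoires, ledger=ledger, config=config
    )


def _plant_overlap(
    rng: np.random.Generator, tumor: Repertoire, normal: Repertoire, fraction: float
) -> None:
    """Re-emit a fraction of tumor clonotypes inside the paired normal sample."""
    k = int(round(fraction * len(tumor.clones)))
    if k == 0:
        return
    tumor_idx = rng.choice(len(tumor.clones), size=k, replace=False)
    replace_idx = rng.choice(len(normal.clones), size=k, replace=False)
    normal_keys = {c.cdr3_nt for c in normal.clones}
    for ti, ni in zip(sorted(tumor_idx), sorted(replace_idx)):
        src = tumor.clones[ti]
        if src.cdr3_nt in normal_keys:
            continue
        normal.clones[ni] = dataclasses.replace(
            src, sample_id=normal.sample_id, clone_count=max(3, src.clone_count // 2)
        )
    normal.ig_mapped_reads = sum(c.clone_count for c in normal.clones)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(sim: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in exactly the formats the readers consume.

    Emits AIRR clone TSVs (one per sample) under ``clones/``, a read-depth
    sidecar, the expression matrix as log2(FPKM+1) TSV, the metadata CSV and
    the ground-truth ledger as JSON.
    """
    outdir = Path(outdir)
    clone_dir = outdir / "clones"
    clone_dir.mkdir(parents=True, exist_ok=True)
    for sid in sorted(sim.repertoires):
        write_clone_table(sim.repertoires[sid], clone_dir / f"{sid}.tsv", "airr")
    depths = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "ig_mapped_reads": rep.ig_mapped_reads,
                "total_reads": rep.total_reads,
            }
            for sid, rep in sorted(sim.repertoires.items())
        ]
    )
    paths = {
        "clone_dir": clone_dir,
        "read_depths": outdir / "read_depths.tsv",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.csv",
        "ledger": outdir / "ledger.json",
    }
    if len(depths):
        depths.to_csv(paths["read_depths"], sep="\t", index=False)
    sim.tables.expression.to_csv(paths["expression"], sep="\t")
    sim.tables.metadata.reset_index().to_csv(paths["metadata"], index=False)
    with open(paths["ledger"], "w") as fh:
        json.dump(sim.ledger, fh, indent=1, sort_keys=True)
    return paths
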