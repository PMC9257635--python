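"""Pipeline configuration and stage runners behind the command-line interface.

Each stage reads the shared :class:`PipelineConfig`, writes its module's
outputs into the run directory, and appends a manifest recording the config
hash, package version, seed and machine-readable warnings. Reruns with an
identical config and inputs produce identical output trees (the manifest
carries no timestamps for this reason).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clone_io import (
    CohortTables,
    Repertoire,
    apply_read_depths,
    filter_repertoire,
    read_clone_table,
    read_cohort_tables,
    read_read_depths,
)
from .exceptions import AnalysisError, ConfigError
from . import metrics as _metrics
from . import shm_csr as _shm
from . import simulate as _sim
from .survival import (
    Biomarker,
    GeneRatio,
    GeneSum,
    IGH_GENES,
    IGHG_GENES,
    MarkerStratification,
    RepertoireMetric,
    compute_biomarker,
    subtype_combined_stratification,
)


@dataclass
class PipelineConfig:
    """All thresholds, paths and gene lists for a pipeline run."""

    seed: int = 0
    dialect: str = "airr"
    clone_dir: str | None = None
    read_depths: str | None = None
    metadata: str | None = None
    expression: str | None = None
    expression_scale: str = "log2fpkm1"
    tumor_suffix: str = "_T"
    normal_suffix: str = "_N"
    min_ig_reads: int = 500
    min_clone_count: int = 3
    min_prop: float = 0.15
    min_group_n: int = 20
    ratio_eps: float = 0.01
    sharing_key: str = "cdr3_aa"
    survival_markers: tuple = ("IGH_sum", "IGHG_sum", "IGHG2_MS4A1_ratio", "IGH_MS4A1_ratio")
    covariates: tuple = ("gender", "age", "smoking", "drinking", "stage", "infiltration")
    subtype_marker: str = "IGHG2_MS4A1_ratio"
    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.dialect not in ("airr", "mixcr"):
            raise ConfigError(f"unknown dialect {self.dialect!r}")
        if self.expression_scale not in ("fpkm", "log2fpkm1"):
            raise ConfigError(f"unknown expression scale {self.expression_scale!r}")
        if self.sharing_key not in ("cdr3_aa", "cdr3_nt"):
            raise ConfigError(f"unknown sharing key {self.sharing_key!r}")
        if not (0 < self.min_prop <= 0.5):
            raise ConfigError(f"min_prop must lie in (0, 0.5], got {self.min_prop}")
        for name in ("min_ig_reads", "min_clone_count", "min_group_n"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.ratio_eps < 0:
            raise ConfigError("ratio_eps must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("survival_markers", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        # relative input paths resolve against the config file's directory,
        # keeping derived configs relocatable
        for key in ("clone_dir", "read_depths", "metadata", "expression"):
            if raw.get(key):
                p = Path(raw[key])
                if not p.is_absolute():
                    raw[key] = str(path.parent / p)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["survival_markers"] = list(self.survival_markers)
        data["covariates"] = list(self.covariates)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def sha256(self) -> str:
        """Hash of the analysis-relevant settings (input/output locations are
        excluded so relocated but otherwise identical runs hash identically)."""
        data = dataclasses.asdict(self)
        for path_field in ("clone_dir", "read_depths", "metadata", "expression"):
            data.pop(path_field, None)
        data["survival_markers"] = list(self.survival_markers)
        data["covariates"] = list(self.covariates)
        canonical = json.dumps(data, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def marker_definitions(cfg: PipelineConfig) -> dict[str, object]:
    eps = cfg.ratio_eps
    return {
        "IGH_sum": GeneSum(IGH_GENES, name="IGH_sum"),
        "IGHG_sum": GeneSum(IGHG_GENES, name="IGHG_sum"),
        "IGHG2_MS4A1_ratio": GeneRatio(("IGHG2",), "MS4A1", eps=eps, name="IGHG2_MS4A1_ratio"),
        "IGH_MS4A1_ratio": GeneRatio(IGH_GENES, "MS4A1", eps=eps, name="IGH_MS4A1_ratio"),
        "clonality": RepertoireMetric("clonality", name="clonality"),
        "mutation_ratio": RepertoireMetric("mutation_ratio", name="mutation_ratio"),
    }


def _sample_info(cfg: PipelineConfig, sample_id: str) -> tuple[str, str]:
    if sample_id.endswith(cfg.tumor_suffix):
        return sample_id[: -len(cfg.tumor_suffix)], "tumor"
    if sample_id.endswith(cfg.normal_suffix):
        return sample_id[: -len(cfg.normal_suffix)], "normal"
    return sample_id, "tumor"


def load_repertoires(cfg: PipelineConfig) -> dict[str, Repertoire]:
    """Read, depth-annotate and filter every clone table in the input dir."""
    if not cfg.clone_dir:
        raise ConfigError("clone_dir not set in config")
    clone_dir = Path(cfg.clone_dir)
    paths = sorted(clone_dir.glob("*.tsv"))
    if not paths:
        raise ConfigError(f"no clone tables (*.tsv) under {clone_dir}")
    depths = read_read_depths(cfg.read_depths) if cfg.read_depths else None
    out: dict[str, Repertoire] = {}
    for path in paths:
        patient, tissue = _sample_info(cfg, path.stem)
        rep = read_clone_table(path, cfg.dialect, patient_id=patient, tissue=tissue)
        if depths is not None:
            rep = apply_read_depths(rep, depths)
        out[rep.sample_id] = filter_repertoire(
            rep, min_ig_reads=cfg.min_ig_reads, min_clone_count=cfg.min_clone_count
        )
    return out


def load_cohort(cfg: PipelineConfig) -> CohortTables:
    if not cfg.metadata or not cfg.expression:
        raise ConfigError("metadata/expression paths not set in config")
    expression = pd.read_csv(cfg.expression, sep="\t", index_col=0, nrows=0)
    sample_map = {s: _sample_info(cfg, s)[0] for s in expression.columns}
    return read_cohort_tables(
        cfg.metadata, cfg.expression, scale=cfg.expression_scale, sample_map=sample_map
    )


def write_manifest(
    outdir: Path, cfg: PipelineConfig, subcommand: str, warnings: list[str]
) -> None:
    manifest = {
        "subcommand": subcommand,
        "config_sha256": cfg.sha256(),
        "seed": cfg.seed,
        "tibrep_version": __version__,
        "warnings": sorted(warnings),
    }
    with open(outdir / f"manifest_{subcommand}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def run_simulate(cfg: PipelineConfig, outdir: Path) -> PipelineConfig:
    """Simulate a cohort, write its files, and emit a config pointing at them."""
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(cfg.simulate)
    rep_overrides = overrides.pop("repertoire", {})
    sim_cfg = _sim.CohortSimConfig(seed=cfg.seed, **overrides)
    if rep_overrides:
        sim_cfg.repertoire = dataclasses.replace(sim_cfg.repertoire, **rep_overrides)
    sim = _sim.simulate_cohort(sim_cfg)
    data_dir = outdir / "data"
    paths = _sim.write_cohort(sim, data_dir)
    derived = dataclasses.replace(
        cfg,
        clone_dir=str(paths["clone_dir"].relative_to(outdir)),
        read_depths=str(paths["read_depths"].relative_to(outdir))
        if paths["read_depths"].exists()
        else None,
        metadata=str(paths["metadata"].relative_to(outdir)),
        expression=str(paths["expression"].relative_to(outdir)),
        expression_scale="log2fpkm1",
    )
    derived.to_yaml(outdir / "pipeline_config.yaml")
    write_manifest(outdir, cfg, "simulate", [])
    return derived


def run_qc(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    outdir.mkdir(parents=True, exist_ok=True)
    reps = load_repertoires(cfg)
    rows = [
        {
            "sample_id": sid,
            "patient_id": rep.patient_id,
            "tissue": rep.tissue,
            "n_rows": rep.qc.n_rows,
            "n_clones_retained": rep.n_clones,
            "n_dropped_empty_cdr3": rep.qc.n_dropped_empty_cdr3,
            "n_row_errors": rep.qc.n_row_errors,
            "n_below_min_count": rep.qc.n_below_min_count,
            "ig_mapped_reads": rep.ig_mapped_reads,
            "total_reads": rep.total_reads if rep.total_reads is not None else "",
            "qc_pass": rep.qc_pass,
        }
        for sid, rep in sorted(reps.items())
    ]
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    write_manifest(outdir, cfg, "qc", [])
    return report


def run_metrics(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    reps = {s: r for s, r in load_repertoires(cfg).items() if r.qc_pass}
    warnings: list[str] = []
    per_sample: dict[str, dict] = {}
    usage_rows, length_rows = [], []
    for sid, rep in sorted(reps.items()):
        entry: dict = {
            "patient_id": rep.patient_id,
            "tissue": rep.tissue,
            "n_clones": rep.n_clones,
        }
        try:
            entry["total_abundance"] = _metrics.total_abundance(rep)
            entry["clonality"] = _metrics.clonality(rep)
            vu = _metrics.v_usage(rep)
            ju = _metrics.j_usage(rep)
            for gene, frac in vu.entries.items():
                usage_rows.append(
                    {"sample_id": sid, "segment": "V", "gene": gene, "fraction": frac}
                )
            for gene, frac in ju.entries.items():
                usage_rows.append(
                    {"sample_id": sid, "segment": "J", "gene": gene, "fraction": frac}
                )
            for length, frac in _metrics.cdr3_length_distribution(rep).items():
                length_rows.append(
                    {"sample_id": sid, "cdr3_length_aa": length, "fraction": frac}
                )
            profile = _metrics.isotype_profile(rep)
            entry["isotype_counts"] = profile.subclass_counts.to_dict()
            entry["class_counts"] = profile.class_counts.to_dict()
            if profile.cpm is not None:
                entry["isotype_cpm"] = {
                    k: round(v, 6) for k, v in profile.cpm.to_dict().items()
                }
        except AnalysisError as exc:
            warnings.append(f"{sid}: {exc}")
        per_sample[sid] = entry
    pairing: dict[str, dict[str, str]] = {}
    for sid, rep in reps.items():
        pairing.setdefault(rep.patient_id, {})[rep.tissue] = sid
    sharing = {}
    for patient, pair in sorted(pairing.items()):
        if "tumor" in pair and "normal" in pair:
            t, n = reps[pair["tumor"]], reps[pair["normal"]]
            try:
                sc = _metrics.shared_clones(t, n, key=cfg.sharing_key)
                sharing[patient] = {
                    "jaccard": _metrics.jaccard_index(t, n, key=cfg.sharing_key),
                    "n_shared": sc.n_shared,
                    "fraction_of_union": sc.fraction_of_union,
                    "n_tumor": sc.n_a,
                    "n_normal": sc.n_b,
                }
            except AnalysisError as exc:
                warnings.append(f"{patient}: {exc}")
    bundle = {"samples": per_sample, "paired_sharing": sharing}
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True, default=float)
    pd.DataFrame(usage_rows).to_csv(outdir / "gene_usage.tsv", sep="\t", index=False)
    pd.DataFrame(length_rows).to_csv(outdir / "cdr3_lengths.tsv", sep="\t", index=False)
    write_manifest(outdir, cfg, "metrics", warnings)
    return bundle


def run_shm(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    outdir.mkdir(parents=True, exist_ok=True)
    reps = {s: r for s, r in load_repertoires(cfg).items() if r.qc_pass}
    warnings: list[str] = []
    summary_rows, lineage_frames = [], []
    for sid, rep in sorted(reps.items()):
        try:
            lineages = _shm.build_lineages(rep)
            ms = _shm.mutation_ratio(rep, lineages=lineages)
            summary_rows.append(
                {
                    "sample_id": sid,
                    "tissue": rep.tissue,
                    "n_clonotypes": ms.n_clonotypes,
                    "n_variants": ms.n_variants,
                    "mutation_ratio": ms.ratio,
                }
            )
            frame = _shm.lineages_to_frame(lineages)
            frame.insert(0, "sample_id", sid)
            lineage_frames.append(frame)
        except AnalysisError as exc:
            warnings.append(f"{sid}: {exc}")
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "mutation_ratio.tsv", sep="\t", index=False)
    if lineage_frames:
        pd.concat(lineage_frames, ignore_index=True).to_csv(
            outdir / "lineages.tsv", sep="\t", index=False
        )
    write_manifest(outdir, cfg, "shm", warnings)
    return summary


def run_csr(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    outdir.mkdir(parents=True, exist_ok=True)
    reps = {s: r for s, r in load_repertoires(cfg).items() if r.qc_pass}
    frames = []
    for sid, rep in sorted(reps.items()):
        graph = _shm.csr_cooccurrence(rep)
        frame = graph.to_frame()
        frame.insert(0, "sample_id", sid)
        frames.append(frame)
    edges = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["sample_id", "subclass_a", "subclass_b", "count", "ratio"])
    )
    edges.to_csv(outdir / "csr_edges.tsv", sep="\t", index=False)
    write_manifest(outdir, cfg, "csr", [])
    return edges


def _result_payload(res) -> dict:
    return {
        "cutpoint": res.cutpoint,
        "cutpoint_selected": res.cutpoint_selected,
        "n_low": res.n_low,
        "n_high": res.n_high,
        "logrank_chi2": res.logrank_chi2,
        "logrank_p": res.logrank_p,
        "n_excluded": res.n_excluded,
        "warnings": res.warnings,
        "cox": {
            cov: {k: float(row[k]) for k in ("coef", "se", "hr", "hr_lower", "hr_upper", "p")}
            for cov, row in res.cox_summary.iterrows()
        },
    }


def run_survival(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = load_cohort(cfg)
    defs = marker_definitions(cfg)
    needs_reps = any(
        isinstance(defs[m], RepertoireMetric) for m in cfg.survival_markers if m in defs
    )
    reps = None
    if needs_reps and cfg.clone_dir:
        reps = {
            s: r
            for s, r in load_repertoires(cfg).items()
            if r.qc_pass and r.tissue == "tumor"
        }
    warnings: list[str] = []
    covariates = tuple(
        c for c in cfg.covariates if c in tables.metadata.columns
    )
    if set(covariates) != set(cfg.covariates):
        missing = set(cfg.covariates) - set(covariates)
        warnings.append(f"covariate(s) absent from metadata: {', '.join(sorted(missing))}")
    payload: dict = {"markers": {}, "subtype_combined": None}
    km_frames, cox_frames = [], []
    for marker_name in cfg.survival_markers:
        if marker_name not in defs:
            warnings.append(f"unknown marker {marker_name!r} skipped")
            continue
        try:
            biomarker = compute_biomarker(tables, defs[marker_name], repertoires=reps)
            model = MarkerStratification.from_cohort(
                tables, biomarker, covariates,
                min_prop=cfg.min_prop, min_group_n=cfg.min_group_n,
            )
            res = model.fit()
        except AnalysisError as exc:
            warnings.append(f"{marker_name}: {exc}")
            continue
        payload["markers"][marker_name] = _result_payload(res)
        km = res.km_frame()
        km.insert(0, "marker", marker_name)
        km_frames.append(km)
        cox = res.cox_summary.reset_index()
        cox.insert(0, "marker", marker_name)
        cox_frames.append(cox)
        warnings.extend(f"{marker_name}: {w}" for w in res.warnings)
    if (
        cfg.subtype_marker
        and cfg.subtype_marker in defs
        and "subtype" in tables.metadata.columns
        and tables.metadata["subtype"].notna().any()
    ):
        try:
            biomarker = compute_biomarker(tables, defs[cfg.subtype_marker], repertoires=reps)
            combo = subtype_combined_stratification(
                tables, biomarker, covariates,
                min_prop=cfg.min_prop, min_group_n=cfg.min_group_n,
            )
            payload["subtype_combined"] = {
                "marker": cfg.subtype_marker,
                "full": _result_payload(combo.full),
                "per_subtype": {s: _result_payload(r) for s, r in combo.per_subtype.items()},
                "pooled": _result_payload(combo.pooled) if combo.pooled else None,
                "pooled_subtypes": list(combo.pooled_subtypes),
                "skipped": combo.skipped,
            }
            warnings.extend(f"subtype {s}: skipped ({r})" for s, r in combo.skipped.items())
        except AnalysisError as exc:
            warnings.append(f"subtype_combined: {exc}")
    with open(outdir / "survival.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=float)
    if km_frames:
        pd.concat(km_frames, ignore_index=True).to_csv(
            outdir / "km_curves.tsv", sep="\t", index=False
        )
    if cox_frames:
        pd.concat(cox_frames, ignore_index=True).to_csv(
            outdir / "cox.tsv", sep="\t", index=False
        )
    write_manifest(outdir, cfg, "survival", warnings)
    return payload


def run_all(cfg: PipelineConfig, outdir: Path) -> None:
    """Chain qc -> metrics -> shm -> csr -> survival into one run directory."""
    run_qc(cfg, outdir / "qc")
    run_metrics(cfg, outdir / "metrics")
    run_shm(cfg, outdir / "shm")
    run_csr(cfg, outdir / "csr")
    run_survival(cfg, outdir / "survival")
    write_manifest(outdir, cfg, "all", [])
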