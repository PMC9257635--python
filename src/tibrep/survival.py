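"""Biomarkers and optimal-cutpoint survival stratification.

The central object is :class:`MarkerStratification`, a model in the
statsmodels mould: construct it from a continuous per-patient marker plus
survival outcomes (and optional clinical covariates), call :meth:`fit`, and
receive a :class:`StratificationResult` carrying the selected cutpoint, group
sizes, Kaplan-Meier curves, the log-rank test and multivariable Cox hazard
ratios with confidence intervals, plus a ``summary()`` table.

Markers
-------
Expression-derived biomarkers follow the conventions of immunoglobulin
bulk-RNA-seq profiling: gene sums over FPKM values (e.g. the IGH sum over
IGHG1-4, IGHA1-2, IGHD, IGHM), and plasma-cell ratios such as IGHG2:MS4A1
(IgG2-secreting plasma cells relative to CD20+ non-plasma B cells), computed
on the FPKM scale with a small denominator pseudocount. Repertoire-derived
markers (clonality, mutation ratio, CSR pair shares) plug into the same
interface.

Cutpoint selection
------------------
The cutpoint is the maximally selected rank statistic: over all splits at
observed marker values that leave both groups at least
``max(min_prop * n, min_group_n)`` patients, the split maximizing the
absolute standardized log-rank statistic is chosen (ties toward the smaller
cutpoint; the returned value is the midpoint between the boundary
observations). The log-rank p reported at the selected cutpoint is the plain
(uncorrected) test and is therefore anti-conservative — a standing warning,
documented rather than corrected, matching common practice for this family
of analyses.

Kaplan-Meier and Cox proportional-hazards fits are delegated to lifelines
(Efron tie handling for Cox).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank

from .clone_io import CohortTables, Repertoire
from .exceptions import AnalysisError
from . import metrics as _metrics
from . import shm_csr as _shm_csr

SELECTION_WARNING = (
    "log-rank p at a selected cutpoint is anti-conservative "
    "(maximally selected statistic; no selection correction applied)"
)

#: Heavy-chain genes entering the IGH expression sum.
IGH_GENES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGHD", "IGHM")
IGHG_GENES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4")

STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSum:
    """Sum of FPKM values over a gene list."""

    genes: tuple[str, ...]
    name: str = ""


@dataclass(frozen=True)
class GeneRatio:
    """FPKM sum of numerator genes over a denominator gene (+ pseudocount)."""

    numerator: tuple[str, ...]
    denominator: str
    eps: float = 0.01
    name: str = ""


@dataclass(frozen=True)
class RepertoireMetric:
    """A per-sample repertoire statistic used as a marker.

    ``metric`` is one of "clonality", "mutation_ratio", or "csr_ratio"
    (the latter requires ``pair``).
    """

    metric: str
    pair: tuple[str, str] | None = None
    name: str = ""


@dataclass
class Biomarker:
    """A named per-patient marker with its declarative definition."""

    name: str
    values: pd.Series
    definition: object

    def __post_init__(self) -> None:
        finite = np.isfinite(self.values.astype(float))
        if not finite.all():
            raise ValueError(
                f"biomarker {self.name!r} has non-finite values for "
                f"{list(self.values.index[~finite])[:5]}"
            )


def compute_biomarker(
    tables: CohortTables,
    definition: GeneSum | GeneRatio | RepertoireMetric,
    repertoires: Mapping[str, Repertoire] | None = None,
) -> Biomarker:
    """Evaluate a marker definition to per-patient values.

    Expression markers are computed on the FPKM scale (log2(FPKM+1) inputs
    are back-transformed per the cohort's scale flag). Repertoire markers
    require per-sample repertoires; samples map to patients via the cohort's
    sample map.
    """
    if isinstance(definition, (GeneSum, GeneRatio)):
        fpkm = tables.expression_fpkm()
        genes = list(
            definition.genes if isinstance(definition, GeneSum) else definition.numerator
        )
        check = genes + ([definition.denominator] if isinstance(definition, GeneRatio) else [])
        missing = [g for g in check if g not in fpkm.index]
        if missing:
            raise AnalysisError(f"expression table missing gene(s): {', '.join(missing)}")
        numerator = fpkm.loc[genes].sum(axis=0)
        if isinstance(definition, GeneSum):
            values = numerator
            default_name = "+".join(genes) + "_sum"
        else:
            den = fpkm.loc[definition.denominator]
            if definition.eps == 0 and (den == 0).any():
                raise AnalysisError(
                    f"zero {definition.denominator} FPKM with eps=0: ratio undefined"
                )
            values = numerator / (den + definition.eps)
            default_name = "+".join(genes) + f":{definition.denominator}"
        values = values.rename(index=tables.patient_of)
    elif isinstance(definition, RepertoireMetric):
        if repertoires is None:
            raise AnalysisError("repertoire metric marker requires repertoires")
        out = {}
        for sample_id, rep in repertoires.items():
            if not rep.qc_pass:
                continue
            if definition.metric == "clonality":
                val = _metrics.clonality(rep)
            elif definition.metric == "mutation_ratio":
                val = _shm_csr.mutation_ratio(rep).ratio
            elif definition.metric == "csr_ratio":
                if definition.pair is None:
                    raise AnalysisError("csr_ratio marker requires a subclass pair")
                val = _shm_csr.csr_ratio(rep, definition.pair)
            else:
                raise AnalysisError(f"unknown repertoire metric {definition.metric!r}")
            out[tables.patient_of(sample_id)] = val
        values = pd.Series(out, dtype=float)
        default_name = definition.metric
    else:
        raise AnalysisError(f"unknown marker definition {type(definition).__name__}")
    name = getattr(definition, "name", "") or default_name
    return Biomarker(name=name, values=values.astype(float), definition=definition)


# ---------------------------------------------------------------------------
# survival primitives
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """A Kaplan-Meier step function with at-risk counts."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.timeline,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "group": self.label,
            }
        )


def km_estimator(
    times: Iterable[float], events: Iterable[int], label: str = ""
) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate; deaths precede censorings at ties."""
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    if t.size == 0:
        raise AnalysisError("empty input to Kaplan-Meier estimator")
    if t.size != e.size:
        raise AnalysisError("times and events differ in length")
    if (t < 0).any():
        raise AnalysisError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=label or "KM")
    timeline = np.asarray(kmf.survival_function_.index, dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return KMCurve(timeline=timeline, survival=survival, at_risk=at_risk, label=label)


def logrank_test(
    group_labels: Iterable, times: Iterable[float], events: Iterable[int]
) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi2, p) on 1 df."""
    g = np.asarray(list(group_labels))
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise AnalysisError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    a, b = (g == labels[0]), (g == labels[1])
    if a.sum() == 0 or b.sum() == 0:
        raise AnalysisError("log-rank test with an empty group")
    res = _lifelines_logrank(t[a], t[b], e[a], e[b])
    return float(res.test_statistic), float(res.p_value)


def _standardized_logrank(
    e_sorted: np.ndarray,
    g_sorted: np.ndarray,
    first_idx: np.ndarray,
    n: int,
) -> float:
    """Standardized log-rank statistic Z = (O-E)/sqrt(V) for the flagged group.

    Operates on event flags and group membership already sorted by time;
    ``first_idx`` marks the first position of each distinct time.
    """
    sfx = np.cumsum(g_sorted[::-1].astype(float))[::-1]
    n_k = (n - first_idx).astype(float)
    n1_k = sfx[first_idx]
    d_k = np.add.reduceat(e_sorted.astype(float), first_idx)
    d1_k = np.add.reduceat((e_sorted * g_sorted).astype(float), first_idx)
    has_event = d_k > 0
    n_k, n1_k, d_k, d1_k = n_k[has_event], n1_k[has_event], d_k[has_event], d1_k[has_event]
    if n_k.size == 0:
        return 0.0
    o_minus_e = float((d1_k - d_k * n1_k / n_k).sum())
    multi = n_k > 1
    frac = n1_k[multi] / n_k[multi]
    var = float(
        (d_k[multi] * frac * (1.0 - frac) * (n_k[multi] - d_k[multi]) / (n_k[multi] - 1.0)).sum()
    )
    if var <= 0:
        return 0.0
    return o_minus_e / np.sqrt(var)


@dataclass
class CutpointResult:
    """Selected cutpoint with its standardized log-rank statistic."""

    cutpoint: float
    statistic: float  # |Z| at the selected split
    z: float
    n_low: int
    n_high: int

    def __float__(self) -> float:
        return self.cutpoint


def optimal_cutpoint(
    marker: Iterable[float] | Biomarker,
    times: Iterable[float],
    events: Iterable[int],
    min_prop: float = 0.15,
    min_group_n: int = 20,
) -> CutpointResult:
    """Maximally selected rank-statistic cutpoint for a continuous marker.

    Candidate splits lie between distinct adjacent observed marker values and
    must leave both groups at least ``max(ceil(min_prop * n), min_group_n)``
    patients. The admissible split maximizing |Z| of the standardized
    log-rank statistic wins; ties break toward the smaller cutpoint. Raises
    :class:`AnalysisError` when no admissible split exists (e.g. a constant
    marker or too few patients).
    """
    if isinstance(marker, Biomarker):
        marker = marker.values
    m = np.asarray(list(marker), dtype=float)
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    n = m.size
    if not (n == t.size == e.size):
        raise AnalysisError("marker, times and events differ in length")
    if not np.isfinite(m).all():
        raise AnalysisError("non-finite marker values; drop missing patients first")
    gmin = max(int(np.ceil(min_prop * n)), int(min_group_n))
    if 2 * gmin > n:
        raise AnalysisError("no admissible split: cohort smaller than twice the group minimum")
    order_m = np.argsort(m, kind="stable")
    m_sorted = m[order_m]
    time_order = np.argsort(t, kind="stable")
    t_s, e_s = t[time_order], e[time_order]
    first_idx = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    best_k = -1
    best_abs = -np.inf
    best_z = 0.0
    lowmask = np.zeros(n, dtype=bool)
    for k in range(gmin, n - gmin + 1):
        if m_sorted[k - 1] >= m_sorted[k]:
            continue
        lowmask[:] = False
        lowmask[order_m[:k]] = True
        z = _standardized_logrank(e_s, lowmask[time_order], first_idx, n)
        if abs(z) > best_abs + 1e-12:
            best_abs = abs(z)
            best_z = z
            best_k = k
    if best_k < 0:
        raise AnalysisError("no admissible split: marker constant within group limits")
    cut = 0.5 * (m_sorted[best_k - 1] + m_sorted[best_k])
    return CutpointResult(
        cutpoint=float(cut),
        statistic=float(best_abs),
        z=float(best_z),
        n_low=best_k,
        n_high=n - best_k,
    )


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "os_time",
    event_col: str = "os_event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) via lifelines.

    Returns one row per covariate: coef, se, hr (= exp(coef)), Wald 95% CI on
    the HR scale, and p. Raises :class:`AnalysisError` for constant
    covariates, too few events, or non-convergence (with diagnostics).
    """
    covs = [c for c in data.columns if c not in (duration_col, event_col)]
    if not covs:
        raise AnalysisError("no covariates to fit")
    constant = [c for c in covs if data[c].nunique(dropna=True) <= 1]
    if constant:
        raise AnalysisError(f"constant covariate(s): {', '.join(constant)}")
    n_events = int(data[event_col].sum())
    if n_events < len(covs):
        raise AnalysisError(
            f"{n_events} events for {len(covs)} covariates: model underdetermined"
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise AnalysisError(f"Cox fit failed to converge: {exc}") from exc
    out = cph.summary[
        ["coef", "se(coef)", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].copy()
    out.columns = ["coef", "se", "hr", "hr_lower", "hr_upper", "p"]
    out.index.name = "covariate"
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def encode_stage(stage: pd.Series) -> pd.Series:
    """Encode pTNM stage I-IV (roman or numeric) as ordinal 1-4."""
    def one(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip().upper()
        if s in STAGE_CODES:
            return float(STAGE_CODES[s])
        return float(s)
    return stage.map(one)


@dataclass
class StratificationResult:
    """Fit results of a marker stratification.

    Attributes mirror what a survival figure reports: the cutpoint and group
    sizes, per-group KM curves, the log-rank chi-square/p, and the
    multivariable Cox table (``cox_summary``; the marker's row is named
    ``<marker>_high``). ``hazard_ratio`` is the marker-term HR.
    """

    name: str
    cutpoint: float
    cutpoint_selected: bool
    n_low: int
    n_high: int
    km_low: KMCurve
    km_high: KMCurve
    logrank_chi2: float
    logrank_p: float
    cox_summary: pd.DataFrame
    marker_term: str
    n_excluded: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def group_sizes(self) -> tuple[int, int]:
        return (self.n_low, self.n_high)

    @property
    def hazard_ratio(self) -> float:
        return float(self.cox_summary.loc[self.marker_term, "hr"])

    @property
    def log_hr(self) -> float:
        return float(self.cox_summary.loc[self.marker_term, "coef"])

    @property
    def log_hr_se(self) -> float:
        return float(self.cox_summary.loc[self.marker_term, "se"])

    def km_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.km_low.to_frame(), self.km_high.to_frame()], ignore_index=True
        )

    def summary(self) -> str:
        lines = [
            f"Marker stratification: {self.name}",
            f"  n = {self.n_low + self.n_high} "
            f"(low {self.n_low} / high {self.n_high}), "
            f"cutpoint = {self.cutpoint:.6g}"
            + (" [selected]" if self.cutpoint_selected else " [fixed]"),
            f"  log-rank chi2 = {self.logrank_chi2:.4g}, p = {self.logrank_p:.4g}",
            "  Cox proportional hazards (Efron ties):",
        ]
        tbl = self.cox_summary.copy()
        header = f"    {'covariate':<22}{'HR':>8}{'95% CI':>20}{'p':>10}"
        lines.append(header)
        for cov, row in tbl.iterrows():
            ci = f"[{row['hr_lower']:.3g}, {row['hr_upper']:.3g}]"
            lines.append(f"    {cov:<22}{row['hr']:>8.3g}{ci:>20}{row['p']:>10.3g}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the two KM step curves (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for curve, style in ((self.km_low, "-"), (self.km_high, "--")):
            ax.step(
                curve.timeline, curve.survival, where="post", linestyle=style,
                label=curve.label or "group",
            )
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{self.name} (cutpoint {self.cutpoint:.4g}, "
                     f"log-rank p {self.logrank_p:.3g})")
        ax.legend()
        return ax


class MarkerStratification:
    """Dichotomizing survival model for a continuous per-patient marker.

    Parameters
    ----------
    marker : pd.Series
        Continuous marker values indexed by patient.
    times, events : pd.Series
        Overall-survival time and event indicator (1 = death), same index.
    covariates : pd.DataFrame, optional
        Numeric adjustment covariates for the multivariable Cox model (e.g.
        gender, age, smoking, drinking, stage, infiltration). Stage should be
        ordinal; binaries 0/1; age continuous.
    min_prop, min_group_n
        Admissibility constraints for cutpoint selection.

    Only complete cases (marker, outcome and all covariates present) enter
    the fit; the number excluded is logged on the result.
    """

    def __init__(
        self,
        marker: pd.Series,
        times: pd.Series,
        events: pd.Series,
        covariates: pd.DataFrame | None = None,
        name: str = "marker",
        min_prop: float = 0.15,
        min_group_n: int = 20,
    ) -> None:
        frame = pd.DataFrame({"marker": marker, "os_time": times, "os_event": events})
        if covariates is not None and len(covariates.columns):
            frame = frame.join(covariates.astype(float), how="left")
        complete = frame.dropna()
        self.n_excluded = len(frame) - len(complete)
        self.data = complete
        self.covariate_cols = [
            c for c in complete.columns if c not in ("marker", "os_time", "os_event")
        ]
        self.name = name
        self.min_prop = float(min_prop)
        self.min_group_n = int(min_group_n)
        if not (0 < self.min_prop <= 0.5):
            raise AnalysisError(f"min_prop must lie in (0, 0.5], got {min_prop}")

    @classmethod
    def from_cohort(
        cls,
        tables: CohortTables,
        biomarker: Biomarker,
        covariate_cols: Sequence[str] = (),
        **kwargs,
    ) -> "MarkerStratification":
        """Build the model from cohort tables and a computed biomarker."""
        return cls.from_metadata(tables.metadata, biomarker, covariate_cols, **kwargs)

    @classmethod
    def from_metadata(
        cls,
        md: pd.DataFrame,
        biomarker: Biomarker,
        covariate_cols: Sequence[str] = (),
        **kwargs,
    ) -> "MarkerStratification":
        covs = None
        if covariate_cols:
            missing = [c for c in covariate_cols if c not in md.columns]
            if missing:
                raise AnalysisError(f"metadata missing covariate(s): {', '.join(missing)}")
            covs = md[list(covariate_cols)].copy()
            if "stage" in covs.columns:
                covs["stage"] = encode_stage(covs["stage"])
        return cls(
            marker=biomarker.values.reindex(md.index),
            times=md["os_time"],
            events=md["os_event"],
            covariates=covs,
            name=kwargs.pop("name", biomarker.name),
            **kwargs,
        )

    def fit(self, cutpoint: float | None = None, marker_form: str = "dichotomized") -> StratificationResult:
        """Select (or apply) a cutpoint and fit KM/log-rank plus Cox.

        ``marker_form="continuous"`` skips dichotomization for the Cox term
        (the marker enters standardized); the KM/log-rank part still uses the
        cutpoint.
        """
        df = self.data
        if df.empty:
            raise AnalysisError("no complete cases to fit")
        notes: list[str] = []
        if self.n_excluded:
            notes.append(f"{self.n_excluded} patient(s) excluded (incomplete data)")
        selected = cutpoint is None
        if selected:
            cp = optimal_cutpoint(
                df["marker"], df["os_time"], df["os_event"],
                min_prop=self.min_prop, min_group_n=self.min_group_n,
            )
            cut = cp.cutpoint
            notes.append(SELECTION_WARNING)
            warnings.warn(SELECTION_WARNING, stacklevel=2)
        else:
            cut = float(cutpoint)
        high = df["marker"] > cut
        n_low, n_high = int((~high).sum()), int(high.sum())
        if n_low == 0 or n_high == 0:
            raise AnalysisError(f"cutpoint {cut:.6g} leaves an empty group")
        km_low = km_estimator(
            df.loc[~high, "os_time"], df.loc[~high, "os_event"],
            label=f"{self.name} low (n={n_low})",
        )
        km_high = km_estimator(
            df.loc[high, "os_time"], df.loc[high, "os_event"],
            label=f"{self.name} high (n={n_high})",
        )
        chi2, p = logrank_test(high.to_numpy(), df["os_time"], df["os_event"])
        marker_term = f"{self.name}_high"
        cox_data = df[["os_time", "os_event"] + self.covariate_cols].copy()
        if marker_form == "dichotomized":
            cox_data[marker_term] = high.astype(float)
        elif marker_form == "continuous":
            marker_term = self.name
            std = df["marker"].std(ddof=0)
            if std == 0:
                raise AnalysisError("constant marker cannot enter the Cox model")
            cox_data[marker_term] = (df["marker"] - df["marker"].mean()) / std
        else:
            raise AnalysisError(f"unknown marker_form {marker_form!r}")
        cox = cox_fit(cox_data)
        return StratificationResult(
            name=self.name,
            cutpoint=cut,
            cutpoint_selected=selected,
            n_low=n_low,
            n_high=n_high,
            km_low=km_low,
            km_high=km_high,
            logrank_chi2=chi2,
            logrank_p=p,
            cox_summary=cox,
            marker_term=marker_term,
            n_excluded=self.n_excluded,
            warnings=notes,
        )


@dataclass
class SubtypeStratification:
    """Per-subtype and pooled results for a full-cohort-selected cutpoint."""

    full: StratificationResult
    per_subtype: dict[str, StratificationResult]
    pooled: StratificationResult | None
    pooled_subtypes: tuple[str, ...]
    skipped: dict[str, str]


def subtype_combined_stratification(
    tables: CohortTables,
    biomarker: Biomarker,
    covariate_cols: Sequence[str] = (),
    subtype_col: str = "subtype",
    pool_excluding: Sequence[str] = ("stemness",),
    min_prop: float = 0.15,
    min_group_n: int = 20,
) -> SubtypeStratification:
    """Stratify within molecular subtypes at the full-cohort cutpoint.

    The marker is dichotomized once, by cutpoint selection on the full
    cohort; KM/log-rank and Cox are then reported within each subtype and
    pooled over the non-excluded (by default, non-stemness) subtypes.
    Subtypes too small or degenerate for a fit are skipped with a recorded
    reason.
    """
    md = tables.metadata
    if subtype_col not in md.columns:
        raise AnalysisError(f"metadata missing subtype column {subtype_col!r}")
    full_model = MarkerStratification.from_cohort(
        tables, biomarker, covariate_cols,
        min_prop=min_prop, min_group_n=min_group_n,
    )
    full = full_model.fit()
    cut = full.cutpoint

    def _subset(patients: pd.Index, label: str) -> StratificationResult | None:
        model = MarkerStratification.from_metadata(
            md.loc[patients], biomarker, covariate_cols,
            min_prop=min_prop, min_group_n=min_group_n, name=f"{biomarker.name}|{label}",
        )
        return model.fit(cutpoint=cut)

    per_subtype: dict[str, StratificationResult] = {}
    skipped: dict[str, str] = {}
    for subtype in sorted(md[subtype_col].dropna().unique()):
        patients = md.index[md[subtype_col] == subtype]
        try:
            per_subtype[subtype] = _subset(patients, subtype)
        except AnalysisError as exc:
            skipped[subtype] = str(exc)
            warnings.warn(f"subtype {subtype!r} skipped: {exc}", stacklevel=2)
    pooled_subtypes = tuple(
        s for s in sorted(md[subtype_col].dropna().unique()) if s not in pool_excluding
    )
    pooled = None
    if pooled_subtypes:
        patients = md.index[md[subtype_col].isin(pooled_subtypes)]
        try:
            pooled = _subset(patients, "+".join(pooled_subtypes))
        except AnalysisError as exc:
            skipped["pooled"] = str(exc)
            warnings.warn(f"pooled non-excluded subtypes skipped: {exc}", stacklevel=2)
    return SubtypeStratification(
        full=full,
        per_subtype=per_subtype,
        pooled=pooled,
        pooled_subtypes=pooled_subtypes,
        skipped=skipped,
    )
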