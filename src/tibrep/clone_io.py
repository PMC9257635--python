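"""Clonotype-table ingestion, gene-call resolution and repertoire quality control.

Clone tables are the per-sample output of a V(D)J aligner run on bulk RNA-seq:
one row per clonotype with its CDR3 nucleotide/amino-acid sequence, candidate
V/J/constant-region gene calls and the number of supporting reads. Two dialects
are read and written: the AIRR Rearrangement TSV (``duplicate_count``,
``junction``, ``junction_aa``, ``v_call``, ``j_call``, ``c_call``) and the
MiXCR tab-delimited clone export (``cloneCount``, ``nSeqCDR3``, ``aaSeqCDR3``,
``allVHitsWithScore``, ``allJHitsWithScore``, ``allCHitsWithScore``).

Quality control follows the retention rules used throughout the downstream
statistics: a sample enters cohort analyses only when at least 500 reads map to
the immunoglobulin loci, and individual clonotypes are retained only with at
least 3 supporting reads. Both thresholds are configurable. Excluded samples
are kept loadable (``qc_pass=False``) so paired tumor/normal bookkeeping stays
intact.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .exceptions import FormatError

#: Sentinel returned by :func:`resolve_gene_call` when >= 2 distinct genes remain.
AMBIGUOUS = "AMBIGUOUS"

DEFAULT_MIN_IG_READS = 500
DEFAULT_MIN_CLONE_COUNT = 3

_SUBGROUP_RE = re.compile(r"^(IG[HKL][VDJ]\d+)")
_SCORE_RE = re.compile(r"\([-0-9.Ee+]*\)$")
_NT_RE = re.compile(r"^[ACGT]+$")

MIXCR_COLUMNS = {
    "cloneCount": "clone_count",
    "nSeqCDR3": "cdr3_nt",
    "aaSeqCDR3": "cdr3_aa",
    "allVHitsWithScore": "v_call",
    "allJHitsWithScore": "j_call",
    "allCHitsWithScore": "c_call",
}
AIRR_COLUMNS = {
    "duplicate_count": "clone_count",
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "v_call": "v_call",
    "j_call": "j_call",
    "c_call": "c_call",
}
_DIALECTS = {"mixcr": MIXCR_COLUMNS, "airr": AIRR_COLUMNS}


@dataclass(frozen=True)
class CloneRecord:
    """One clonotype: a unique CDR3 with its gene calls and read support.

    Gene calls are tuples of candidate names as emitted by the aligner
    (allele suffixes and alignment scores are tolerated and stripped during
    resolution). CDR3 sequences are upper-cased on construction; identity
    comparisons are therefore case-insensitive.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_call: tuple[str, ...]
    j_call: tuple[str, ...]
    c_call: tuple[str, ...] = ()
    clone_count: int = 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cdr3_nt", self.cdr3_nt.upper())
        object.__setattr__(self, "cdr3_aa", self.cdr3_aa.upper())
        object.__setattr__(self, "v_call", tuple(self.v_call))
        object.__setattr__(self, "j_call", tuple(self.j_call))
        object.__setattr__(self, "c_call", tuple(self.c_call))
        if self.clone_count < 1:
            raise ValueError(f"clone_count must be >= 1, got {self.clone_count}")
        if len(self.cdr3_nt) < 3:
            raise ValueError("cdr3_nt shorter than one codon")
        if not _NT_RE.match(self.cdr3_nt):
            raise ValueError(f"cdr3_nt contains non-ACGT characters: {self.cdr3_nt!r}")

    def translate(self) -> str:
        """Translate cdr3_nt in frame 0 (trailing partial codon dropped)."""
        trimmed = self.cdr3_nt[: 3 * (len(self.cdr3_nt) // 3)]
        return str(Seq(trimmed).translate())

    @property
    def is_consistent(self) -> bool:
        """Whether cdr3_aa equals the frame-0 translation of cdr3_nt.

        Records without an amino-acid sequence are trivially consistent;
        inconsistent records are flagged in the QC report, not rejected.
        """
        if not self.cdr3_aa:
            return True
        return len(self.cdr3_nt) % 3 == 0 and self.translate() == self.cdr3_aa


@dataclass
class QCReport:
    """Row-level bookkeeping from parsing and filtering one clone table."""

    n_rows: int = 0
    n_dropped_empty_cdr3: int = 0
    n_row_errors: int = 0
    n_below_min_count: int = 0
    n_inconsistent: int = 0
    messages: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.n_rows} rows, {self.n_dropped_empty_cdr3} dropped (empty CDR3), "
            f"{self.n_row_errors} row errors, {self.n_below_min_count} below count "
            f"threshold, {self.n_inconsistent} nt/aa-inconsistent"
        )


@dataclass
class Repertoire:
    """A sample's clonotypes plus the read-depth context used for QC and CPM.

    ``ig_mapped_reads`` defaults to the sum of clone counts when no aligner
    report (sidecar read-depth table) is supplied. ``total_reads`` is the
    sample's total sequencing depth and is required only for clonotypes-per-
    million (CPM) quantities.
    """

    sample_id: str
    clones: list[CloneRecord]
    patient_id: str = ""
    tissue: str = "tumor"
    ig_mapped_reads: int | None = None
    total_reads: int | None = None
    qc_pass: bool = False
    qc: QCReport = field(default_factory=QCReport)

    def __post_init__(self) -> None:
        if self.ig_mapped_reads is None:
            self.ig_mapped_reads = sum(c.clone_count for c in self.clones)
        if self.total_reads is not None and self.total_reads < self.ig_mapped_reads:
            raise ValueError(
                f"total_reads ({self.total_reads}) < ig_mapped_reads "
                f"({self.ig_mapped_reads}) for sample {self.sample_id}"
            )

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def __len__(self) -> int:
        return len(self.clones)


def strip_allele(name: str) -> str:
    """Drop an IMGT allele suffix: ``IGHV3-23*01`` -> ``IGHV3-23``."""
    return name.split("*", 1)[0].strip()


def subgroup(name: str) -> str:
    """Collapse a gene name to its subgroup (family) prefix: ``IGHV3-23`` -> ``IGHV3``.

    Names outside the IG V/D/J grammar (e.g. constant-region genes) are
    returned allele-stripped but otherwise unchanged.
    """
    bare = strip_allele(name)
    m = _SUBGROUP_RE.match(bare)
    return m.group(1) if m else bare


def resolve_gene_call(call: Iterable[str], level: str = "gene") -> str | None:
    """Resolve a candidate gene-call list to a single name, AMBIGUOUS, or None.

    Allele suffixes are stripped before uniqueness testing. At
    ``level="subgroup"`` names are first collapsed to the family prefix, so a
    call that is ambiguous at gene level may still resolve at subgroup level.
    Total function: returns ``None`` for an empty call list.
    """
    if level not in ("gene", "subgroup"):
        raise ValueError(f"unknown resolution level {level!r}")
    names = {strip_allele(c) for c in call if c and c.strip()}
    if level == "subgroup":
        names = {subgroup(n) for n in names}
    if not names:
        return None
    if len(names) == 1:
        return next(iter(names))
    return AMBIGUOUS


def _split_hits(raw: object) -> tuple[str, ...]:
    """Split a comma-separated hit list, stripping MiXCR ``(score)`` suffixes."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ()
    text = str(raw).strip()
    if not text or text.lower() == "nan":
        return ()
    parts = (p.strip() for p in text.split(","))
    return tuple(_SCORE_RE.sub("", p) for p in parts if p)


def _parse_count(raw: object) -> int:
    value = float(raw)
    if not math.isfinite(value) or abs(value - round(value)) > 1e-6:
        raise ValueError(f"unparseable clone count {raw!r}")
    return int(round(value))


def read_clone_table(
    path: str | Path,
    dialect: str,
    sample_id: str | None = None,
    patient_id: str = "",
    tissue: str = "tumor",
) -> Repertoire:
    """Read one per-sample clone table into a :class:`Repertoire`.

    Rows with an empty CDR3 are dropped and counted in the QC report; rows
    with unparseable counts or malformed sequences are collected as row-level
    errors (not fatal). A missing mandatory column raises :class:`FormatError`
    naming the column.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown clone-table dialect {dialect!r}")
    colmap = _DIALECTS[dialect]
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing mandatory column(s) {', '.join(missing)} "
            f"for dialect {dialect!r}"
        )
    if sample_id is None:
        sample_id = path.stem
    qc = QCReport()
    clones: list[CloneRecord] = []
    inv = {v: k for k, v in colmap.items()}
    for _, row in df.iterrows():
        qc.n_rows += 1
        cdr3_nt = row[inv["cdr3_nt"]]
        if cdr3_nt is None or (isinstance(cdr3_nt, float) and math.isnan(cdr3_nt)) or not str(cdr3_nt).strip():
            qc.n_dropped_empty_cdr3 += 1
            continue
        try:
            rec = CloneRecord(
                cdr3_nt=str(cdr3_nt),
                cdr3_aa=str(row[inv["cdr3_aa"]]).strip()
                if isinstance(row[inv["cdr3_aa"]], str)
                else "",
                v_call=_split_hits(row[inv["v_call"]]),
                j_call=_split_hits(row[inv["j_call"]]),
                c_call=_split_hits(row[inv["c_call"]]),
                clone_count=_parse_count(row[inv["clone_count"]]),
                sample_id=sample_id,
            )
        except ValueError as exc:
            qc.n_row_errors += 1
            qc.messages.append(f"row {qc.n_rows}: {exc}")
            continue
        if not rec.is_consistent:
            qc.n_inconsistent += 1
        clones.append(rec)
    qc.messages.append(f"{qc.n_dropped_empty_cdr3} dropped")
    return Repertoire(
        sample_id=sample_id,
        patient_id=patient_id,
        tissue=tissue,
        clones=clones,
        qc=qc,
    )


def write_clone_table(rep: Repertoire, path: str | Path, dialect: str) -> None:
    """Write a repertoire back out in the chosen dialect (round-trips with
    :func:`read_clone_table` up to allele scores, which are never stored)."""
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown clone-table dialect {dialect!r}")
    colmap = _DIALECTS[dialect]
    inv = {v: k for k, v in colmap.items()}
    rows = []
    for c in rep.clones:
        rows.append(
            {
                inv["clone_count"]: c.clone_count,
                inv["cdr3_nt"]: c.cdr3_nt,
                inv["cdr3_aa"]: c.cdr3_aa,
                inv["v_call"]: ",".join(c.v_call),
                inv["j_call"]: ",".join(c.j_call),
                inv["c_call"]: ",".join(c.c_call),
            }
        )
    df = pd.DataFrame(rows, columns=list(colmap.keys()))
    df.to_csv(path, sep="\t", index=False)


def read_read_depths(path: str | Path) -> pd.DataFrame:
    """Read a sidecar read-depth table (sample_id, ig_mapped_reads, total_reads)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "ig_mapped_reads", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"read-depth sidecar missing column(s) {', '.join(sorted(missing))}"
        )
    return df.set_index("sample_id")


def apply_read_depths(rep: Repertoire, depths: pd.DataFrame) -> Repertoire:
    """Override a repertoire's read-depth context from a sidecar table.

    Samples absent from the table are returned unchanged (the clone-count sum
    remains the ig_mapped_reads fallback).
    """
    if rep.sample_id not in depths.index:
        return rep
    row = depths.loc[rep.sample_id]
    return dataclasses.replace(
        rep,
        ig_mapped_reads=int(row["ig_mapped_reads"]),
        total_reads=int(row["total_reads"]),
    )


def filter_repertoire(
    rep: Repertoire,
    min_ig_reads: int = DEFAULT_MIN_IG_READS,
    min_clone_count: int = DEFAULT_MIN_CLONE_COUNT,
) -> Repertoire:
    """Apply the retention rules: drop low-count clones, flag shallow samples.

    Clones below ``min_clone_count`` supporting reads are removed;
    ``qc_pass`` is set False when fewer than ``min_ig_reads`` reads map to the
    Ig loci (the sample is excluded from cohort statistics but remains
    loadable). Idempotent: filtering a filtered repertoire is a no-op.
    """
    kept = [c for c in rep.clones if c.clone_count >= min_clone_count]
    n_dropped = len(rep.clones) - len(kept)
    qc = dataclasses.replace(
        rep.qc,
        n_below_min_count=rep.qc.n_below_min_count + n_dropped,
        messages=list(rep.qc.messages),
    )
    assert rep.ig_mapped_reads is not None
    return dataclasses.replace(
        rep,
        clones=kept,
        qc_pass=rep.ig_mapped_reads >= min_ig_reads,
        qc=qc,
    )


@dataclass
class CohortTables:
    """Patient metadata, expression matrix and the sample-to-patient map.

    ``metadata`` is indexed by patient_id and must carry ``os_time`` (units
    declared by the caller; days or months) and ``os_event`` (0/1); clinical
    covariates (gender, age, smoking, drinking, stage, infiltration, subtype)
    are optional columns. ``expression`` is genes x samples on either the FPKM
    scale (``scale_flag="fpkm"``) or log2(FPKM+1) (``scale_flag="log2fpkm1"``).
    """

    metadata: pd.DataFrame
    expression: pd.DataFrame
    scale_flag: str = "fpkm"
    sample_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scale_flag not in ("fpkm", "log2fpkm1"):
            raise ValueError(f"unknown expression scale {self.scale_flag!r}")
        for col in ("os_time", "os_event"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if (self.metadata["os_time"] < 0).any():
            raise ValueError("negative os_time in metadata")
        if self.scale_flag == "log2fpkm1" and (self.expression.values < 0).any():
            raise ValueError("log2(FPKM+1) expression must be non-negative")
        unknown = [
            s for s in self.expression.columns
            if self.patient_of(s) not in self.metadata.index
        ]
        if unknown:
            raise ValueError(
                f"expression sample(s) with no metadata patient: {unknown[:5]}"
            )

    def patient_of(self, sample_id: str) -> str:
        if self.sample_map is None:
            return sample_id
        return self.sample_map.get(sample_id, sample_id)

    def expression_fpkm(self) -> pd.DataFrame:
        """Expression on the FPKM scale (log2(FPKM+1) inputs back-transformed)."""
        if self.scale_flag == "fpkm":
            return self.expression
        return (2.0 ** self.expression - 1.0).clip(lower=0.0)

    def expression_by_patient(self) -> pd.DataFrame:
        """Expression with columns renamed sample_id -> patient_id."""
        renamed = self.expression.rename(columns=self.patient_of)
        if renamed.columns.duplicated().any():
            dups = renamed.columns[renamed.columns.duplicated()].tolist()
            raise ValueError(f"multiple expression samples per patient: {dups[:5]}")
        return renamed


def read_cohort_tables(
    metadata_csv: str | Path,
    expression_tsv: str | Path,
    scale: str = "fpkm",
    sample_map: Mapping[str, str] | None = None,
) -> CohortTables:
    """Load cohort metadata (CSV, ``patient_id`` column) and a genes x samples
    expression TSV into a :class:`CohortTables`."""
    metadata = pd.read_csv(metadata_csv)
    if "patient_id" not in metadata.columns:
        raise FormatError("cohort metadata missing 'patient_id' column")
    metadata = metadata.set_index("patient_id")
    expression = pd.read_csv(expression_tsv, sep="\t", index_col=0)
    return CohortTables(
        metadata=metadata,
        expression=expression,
        scale_flag=scale,
        sample_map=sample_map,
    )
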