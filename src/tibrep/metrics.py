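"""Repertoire summary statistics.

Everything here is clone-count-weighted descriptive statistics over a single
sample's retained clonotypes (or a pair of samples, for sharing measures):

* abundance and V/J gene-usage fractions, with ambiguous gene calls excluded
  from both numerator and denominator;
* the V-subgroup x J-gene rearrangement matrix;
* the CDR3 length spectrum;
* clone sharing and the Jaccard index between paired samples;
* clonality, defined as 1 - normalized Shannon-Wiener index of the clone
  frequency distribution (0 = evenly distributed/diverse, 1 = monoclonal);
* isotype/subclass profiles with depth-normalized clonotypes-per-million (CPM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .clone_io import AMBIGUOUS, CloneRecord, Repertoire, resolve_gene_call, strip_allele
from .exceptions import AnalysisError

#: Heavy-chain constant-region subclasses, genomic order.
SUBCLASSES = (
    "IGHM", "IGHD", "IGHG3", "IGHG1", "IGHA1", "IGHG2", "IGHG4", "IGHE", "IGHA2",
)
CLASS_OF = {
    "IGHG1": "IGHG", "IGHG2": "IGHG", "IGHG3": "IGHG", "IGHG4": "IGHG",
    "IGHA1": "IGHA", "IGHA2": "IGHA",
    "IGHM": "IGHM", "IGHD": "IGHD", "IGHE": "IGHE",
}
CLASSES = ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE")


def _require_qc(rep: Repertoire) -> None:
    if not rep.qc_pass:
        raise AnalysisError(f"sample {rep.sample_id!r} did not pass repertoire QC")


def _require_clones(rep: Repertoire) -> None:
    if not rep.clones:
        raise AnalysisError(f"no clones after filtering in sample {rep.sample_id!r}")


def clone_chain(clone: CloneRecord) -> str | None:
    """Chain (IGH/IGK/IGL) of a clone, from its first V (or J) gene call."""
    for call in (clone.v_call, clone.j_call):
        for name in call:
            prefix = strip_allele(name)[:3]
            if prefix in ("IGH", "IGK", "IGL"):
                return prefix
    return None


def total_abundance(rep: Repertoire) -> int:
    """Total clone abundance N: the sum of retained clone counts."""
    _require_qc(rep)
    _require_clones(rep)
    return sum(c.clone_count for c in rep.clones)


@dataclass
class UsageTable:
    """Per-gene usage fractions for one segment of one chain.

    Fractions are clone-count weighted and normalized over clones with an
    unambiguously resolved gene, so they sum to 1; genes absent from the
    repertoire are omitted (implied fraction 0).
    """

    entries: pd.Series
    chain: str
    segment: str
    level: str
    basis: str = "clone_counts"

    def to_frame(self) -> pd.DataFrame:
        return self.entries.rename("fraction").rename_axis("gene").reset_index()


def _segment_usage(rep: Repertoire, segment: str, chain: str, level: str) -> UsageTable:
    _require_qc(rep)
    _require_clones(rep)
    weights: dict[str, int] = {}
    for c in rep.clones:
        if clone_chain(c) != chain:
            continue
        call = c.v_call if segment == "V" else c.j_call
        gene = resolve_gene_call(call, level=level)
        if gene is None or gene == AMBIGUOUS:
            continue
        weights[gene] = weights.get(gene, 0) + c.clone_count
    if not weights:
        raise AnalysisError(
            f"no {chain} clones with an unambiguous {segment} gene in "
            f"sample {rep.sample_id!r}"
        )
    total = sum(weights.values())
    entries = pd.Series(weights, dtype=float) / total
    entries = entries.sort_values(ascending=False)
    return UsageTable(entries=entries, chain=chain, segment=segment, level=level)


def v_usage(rep: Repertoire, chain: str = "IGH", level: str = "gene") -> UsageTable:
    """Clone-count-weighted V-gene usage fractions."""
    return _segment_usage(rep, "V", chain, level)


def j_usage(rep: Repertoire, chain: str = "IGH", level: str = "gene") -> UsageTable:
    """Clone-count-weighted J-gene usage fractions."""
    return _segment_usage(rep, "J", chain, level)


def vj_rearrangement(rep: Repertoire, chain: str = "IGH") -> pd.DataFrame:
    """V-subgroup x J-gene rearrangement fractions (cells sum to 1).

    Clones ambiguous at the V-subgroup or J-gene level are excluded from both
    numerator and denominator.
    """
    _require_qc(rep)
    _require_clones(rep)
    cells: dict[tuple[str, str], int] = {}
    for c in rep.clones:
        if clone_chain(c) != chain:
            continue
        v = resolve_gene_call(c.v_call, level="subgroup")
        j = resolve_gene_call(c.j_call, level="gene")
        if v in (None, AMBIGUOUS) or j in (None, AMBIGUOUS):
            continue
        cells[(v, j)] = cells.get((v, j), 0) + c.clone_count
    if not cells:
        raise AnalysisError(
            f"no resolvable {chain} V/J clones in sample {rep.sample_id!r}"
        )
    total = sum(cells.values())
    rows = sorted({v for v, _ in cells})
    cols = sorted({j for _, j in cells})
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for (v, j), w in cells.items():
        mat.loc[v, j] = w / total
    mat.index.name = "v_subgroup"
    mat.columns.name = "j_gene"
    return mat


def cdr3_length_distribution(rep: Repertoire, unit: str = "aa") -> pd.Series:
    """Clone-count-weighted CDR3 length spectrum (fractions sum to 1)."""
    if unit not in ("aa", "nt"):
        raise ValueError(f"unknown CDR3 length unit {unit!r}")
    _require_qc(rep)
    _require_clones(rep)
    weights: dict[int, int] = {}
    for c in rep.clones:
        if unit == "nt":
            length = len(c.cdr3_nt)
        else:
            length = len(c.cdr3_aa) if c.cdr3_aa else len(c.cdr3_nt) // 3
        weights[length] = weights.get(length, 0) + c.clone_count
    total = sum(weights.values())
    out = pd.Series(weights, dtype=float).sort_index() / total
    out.index.name = f"cdr3_length_{unit}"
    return out


def _key_set(rep: Repertoire, key: str) -> frozenset[str]:
    if key not in ("cdr3_aa", "cdr3_nt"):
        raise ValueError(f"unknown sharing key {key!r}")
    return frozenset(getattr(c, key) for c in rep.clones if getattr(c, key))


@dataclass
class SharedClones:
    shared: frozenset[str]
    fraction_of_union: float
    n_a: int
    n_b: int

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def shared_clones(
    rep_a: Repertoire, rep_b: Repertoire, key: str = "cdr3_aa"
) -> SharedClones:
    """Exact-identity clone sharing between two samples on the chosen key.

    Reports the shared set, its fraction of the union, and both set sizes so
    that alternative shared-fraction denominators can be recovered.
    """
    _require_qc(rep_a)
    _require_qc(rep_b)
    a, b = _key_set(rep_a, key), _key_set(rep_b, key)
    union = a | b
    shared = a & b
    frac = len(shared) / len(union) if union else 0.0
    return SharedClones(shared=shared, fraction_of_union=frac, n_a=len(a), n_b=len(b))


def jaccard_index(rep_a: Repertoire, rep_b: Repertoire, key: str = "cdr3_aa") -> float:
    """Unweighted (presence/absence) Jaccard index of unique CDR3 keys."""
    _require_qc(rep_a)
    _require_qc(rep_b)
    a, b = _key_set(rep_a, key), _key_set(rep_b, key)
    union = a | b
    if not union:
        raise AnalysisError("Jaccard index undefined for two empty repertoires")
    return len(a & b) / len(union)


def clonality(rep: Repertoire) -> float:
    """1 - normalized Shannon-Wiener index of the clone frequency distribution.

    With p_i = count_i / N over the S retained clonotypes,
    H = -sum p_i ln p_i and clonality = 1 - H / ln S. Values near 0 indicate
    an even, diverse repertoire; values near 1 an oligoclonal one. A
    single-clone repertoire is defined as maximally oligoclonal (1.0), the
    limit that avoids the 0/0 normalization. The log base cancels in the
    ratio, so the choice of natural log is immaterial.
    """
    _require_qc(rep)
    _require_clones(rep)
    counts = np.asarray([c.clone_count for c in rep.clones], dtype=float)
    s = counts.size
    if s == 1:
        return 1.0
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    value = 1.0 - h / np.log(s)
    return float(min(1.0, max(0.0, value)))


@dataclass
class IsotypeProfile:
    """Clonotype tallies per constant-region class and subclass.

    Class-level tallies are permissive (a clone with any IgG subclass call
    counts toward IGHG); subclass-level tallies are strict (only clones whose
    constant-gene call resolves to exactly one subclass). ``cpm`` is
    clonotypes per million sequencing reads and is ``None`` when the sample's
    total read depth is unknown; use :meth:`require_cpm` to insist on it.
    """

    subclass_counts: pd.Series
    class_counts: pd.Series
    cpm: pd.Series | None
    class_cpm: pd.Series | None
    total_reads: int | None

    def require_cpm(self) -> pd.Series:
        if self.cpm is None:
            raise AnalysisError("total_reads missing: CPM unavailable")
        return self.cpm


def isotype_profile(rep: Repertoire) -> IsotypeProfile:
    """Tally clonotypes per Ig class and subclass, with CPM when depth is known."""
    _require_qc(rep)
    sub_counts = pd.Series(0, index=list(SUBCLASSES), dtype=int)
    cls_counts = pd.Series(0, index=list(CLASSES), dtype=int)
    for c in rep.clones:
        subs = {strip_allele(x) for x in c.c_call}
        subs &= set(SUBCLASSES)
        if not subs:
            continue
        for cls in {CLASS_OF[s] for s in subs}:
            cls_counts[cls] += 1
        if len(subs) == 1:
            sub_counts[next(iter(subs))] += 1
    if rep.total_reads:
        cpm = sub_counts * 1e6 / rep.total_reads
        class_cpm = cls_counts * 1e6 / rep.total_reads
    else:
        cpm = None
        class_cpm = None
    return IsotypeProfile(
        subclass_counts=sub_counts,
        class_counts=cls_counts,
        cpm=cpm,
        class_cpm=class_cpm,
        total_reads=rep.total_reads,
    )


def compare_groups(
    x: Iterable[float],
    y: Iterable[float],
    test: str = "wilcoxon",
    paired: bool = False,
) -> tuple[float, float]:
    """Thin wrapper over standard two-sample tests for cohort comparisons.

    ``test``: "ttest" (Student) or "wilcoxon" (signed-rank when paired,
    rank-sum otherwise). Returns (statistic, p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if test == "ttest":
        res = _scipy_stats.ttest_rel(x, y) if paired else _scipy_stats.ttest_ind(x, y)
    elif test == "wilcoxon":
        res = _scipy_stats.wilcoxon(x, y) if paired else _scipy_stats.ranksums(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
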