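"""Somatic-hypermutation lineages and class-switch co-occurrence.

SHM is approximated at the CDR3 level: within clonotypes sharing a resolved V
and J gene, pairs of CDR3 nucleotide sequences at edit distance exactly 1 (one
substitution, or one single-base insertion/deletion) are linked, and connected
components of that graph are mutation lineages. The most abundant member is
the lineage root; the remaining members are its variants. Requiring shared
V and J avoids conflating convergent CDR3s from unrelated rearrangements.

Class-switch recombination (CSR) is detected as one clonotype observed with
two constant-region subclasses: either a single row whose constant-gene call
resolves to exactly two subclasses, or distinct rows sharing an identical
CDR3nt + V + J but carrying different single subclasses (these are merged
first). Each such clonotype contributes one count to the unordered
subclass-pair edge of the co-occurrence graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd
from Bio.Seq import Seq

from .clone_io import AMBIGUOUS, CloneRecord, Repertoire, resolve_gene_call, strip_allele
from .exceptions import AnalysisError
from .metrics import SUBCLASSES, _require_clones, _require_qc

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
INDEL = "indel"


def _hamming_is_one(a: str, b: str) -> bool:
    """Exactly one substitution between equal-length strings."""
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def _indel_is_one(short: str, long: str) -> bool:
    """`long` equals `short` with exactly one extra base inserted."""
    i = j = 0
    skipped = False
    while i < len(short):
        if short[i] == long[j]:
            i += 1
            j += 1
        else:
            if skipped:
                return False
            skipped = True
            j += 1
    return True


def edit_distance_is_one(a: str, b: str, allow_indel: bool = True) -> bool:
    """Whether two CDR3nt strings differ by exactly one edit."""
    la, lb = len(a), len(b)
    if la == lb:
        return _hamming_is_one(a, b)
    if not allow_indel or abs(la - lb) != 1:
        return False
    return _indel_is_one(a, b) if la < lb else _indel_is_one(b, a)


@dataclass(frozen=True)
class LineageNode:
    """A unique clonotype (resolved V, resolved J, CDR3nt), rows aggregated."""

    cdr3_nt: str
    v_gene: str | None
    j_gene: str | None
    clone_count: int
    records: tuple[CloneRecord, ...]


@dataclass
class Lineage:
    """One SHM lineage: the root clonotype and its 1-edit-linked variants."""

    root: LineageNode
    variants: tuple[LineageNode, ...]

    @property
    def v_gene(self) -> str | None:
        return self.root.v_gene

    @property
    def j_gene(self) -> str | None:
        return self.root.j_gene

    @property
    def size(self) -> int:
        return 1 + len(self.variants)

    @property
    def cdr3_set(self) -> frozenset[str]:
        return frozenset([self.root.cdr3_nt, *(v.cdr3_nt for v in self.variants)])


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _nodes(rep: Repertoire) -> list[LineageNode]:
    """Collapse clone rows into unique (V, J, CDR3nt) clonotype nodes."""
    grouped: dict[tuple[str | None, str | None, str], list[CloneRecord]] = {}
    for c in rep.clones:
        v = resolve_gene_call(c.v_call, level="gene")
        j = resolve_gene_call(c.j_call, level="gene")
        grouped.setdefault((v, j, c.cdr3_nt), []).append(c)
    nodes = []
    for (v, j, cdr3), recs in grouped.items():
        nodes.append(
            LineageNode(
                cdr3_nt=cdr3,
                v_gene=v,
                j_gene=j,
                clone_count=sum(r.clone_count for r in recs),
                records=tuple(recs),
            )
        )
    return nodes


def build_lineages(rep: Repertoire, allow_indel: bool = True) -> list[Lineage]:
    """Cluster clonotypes into SHM lineages by the 1-edit rule.

    Within each resolved (V gene, J gene) bucket, clonotype pairs whose CDR3nt
    differ by exactly one substitution (or, with ``allow_indel``, one
    single-base indel — a deletion in one sequence is an insertion in the
    other) are linked; connected components become lineages. Clonotypes with
    an ambiguous or missing V or J are never linked and appear as singleton
    lineages. The root is the maximal-count member, ties broken toward the
    lexicographically smallest CDR3nt; output order is deterministic.
    """
    _require_qc(rep)
    nodes = _nodes(rep)
    buckets: dict[tuple[str, str], list[int]] = {}
    for idx, node in enumerate(nodes):
        if node.v_gene in (None, AMBIGUOUS) or node.j_gene in (None, AMBIGUOUS):
            continue
        buckets.setdefault((node.v_gene, node.j_gene), []).append(idx)
    dsu = _DSU(len(nodes))
    for members in buckets.values():
        by_len: dict[int, list[int]] = {}
        for idx in members:
            by_len.setdefault(len(nodes[idx].cdr3_nt), []).append(idx)
        for length, idxs in by_len.items():
            for i, j in combinations(idxs, 2):
                if _hamming_is_one(nodes[i].cdr3_nt, nodes[j].cdr3_nt):
                    dsu.union(i, j)
            if allow_indel and (length + 1) in by_len:
                for i in idxs:
                    for j in by_len[length + 1]:
                        if _indel_is_one(nodes[i].cdr3_nt, nodes[j].cdr3_nt):
                            dsu.union(i, j)
    components: dict[int, list[LineageNode]] = {}
    for idx, node in enumerate(nodes):
        components.setdefault(dsu.find(idx), []).append(node)
    lineages = []
    for group in components.values():
        group.sort(key=lambda n: (-n.clone_count, n.cdr3_nt))
        lineages.append(Lineage(root=group[0], variants=tuple(group[1:])))
    lineages.sort(key=lambda l: (l.v_gene or "", l.j_gene or "", l.root.cdr3_nt))
    return lineages


@dataclass
class MutationSummary:
    """Per-sample SHM summary: the mutation ratio plus per-lineage detail."""

    ratio: float
    n_variants: int
    n_clonotypes: int
    per_lineage: pd.DataFrame


def mutation_ratio(
    rep: Repertoire,
    lineages: list[Lineage] | None = None,
    weight: str = "clones",
) -> MutationSummary:
    """Fraction of clonotypes that are SHM variants (non-root lineage members).

    ``weight="clones"`` (default) counts clonotypes; ``weight="reads"``
    weights by clone counts instead. The per-lineage table carries each
    variant's mutation class relative to its root.
    """
    if weight not in ("clones", "reads"):
        raise ValueError(f"unknown weight {weight!r}")
    _require_clones(rep)
    if lineages is None:
        lineages = build_lineages(rep)
    rows = []
    for lid, lin in enumerate(lineages):
        classes = [classify_mutation(lin.root.cdr3_nt, v.cdr3_nt) for v in lin.variants]
        rows.append(
            {
                "lineage_id": lid,
                "v_gene": lin.v_gene,
                "j_gene": lin.j_gene,
                "root_cdr3_nt": lin.root.cdr3_nt,
                "root_count": lin.root.clone_count,
                "n_variants": len(lin.variants),
                "variant_count": sum(v.clone_count for v in lin.variants),
                "n_synonymous": sum(c == SYNONYMOUS for c in classes),
                "n_nonsynonymous": sum(c == NONSYNONYMOUS for c in classes),
                "n_indel": sum(c == INDEL for c in classes),
            }
        )
    detail = pd.DataFrame(rows)
    n_variants = int(detail["n_variants"].sum())
    n_total = int(detail["n_variants"].sum() + len(detail))
    if weight == "clones":
        ratio = n_variants / n_total
    else:
        variant_reads = int(detail["variant_count"].sum())
        total_reads = int(detail["variant_count"].sum() + detail["root_count"].sum())
        ratio = variant_reads / total_reads
    return MutationSummary(
        ratio=ratio,
        n_variants=n_variants,
        n_clonotypes=n_total,
        per_lineage=detail,
    )


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def classify_mutation(root_cdr3_nt: str, variant_cdr3_nt: str) -> str:
    """Classify a 1-edit CDR3 variant as synonymous, nonsynonymous, or indel.

    Equal lengths imply a substitution: both sequences are translated in
    frame 0 and compared. Out-of-frame substitutions (length not divisible by
    3) cannot be judged at the protein level and are classified nonsynonymous
    with a warning. Unequal lengths are indels. Raises
    :class:`AnalysisError` when the pair is not at edit distance 1.
    """
    root = root_cdr3_nt.upper()
    var = variant_cdr3_nt.upper()
    if len(root) == len(var):
        if not _hamming_is_one(root, var):
            raise AnalysisError("sequences are not at edit distance 1")
        if len(root) % 3 != 0:
            warnings.warn(
                "out-of-frame CDR3 substitution classified nonsynonymous",
                stacklevel=2,
            )
            return NONSYNONYMOUS
        return SYNONYMOUS if _translate(root) == _translate(var) else NONSYNONYMOUS
    if not edit_distance_is_one(root, var):
        raise AnalysisError("sequences are not at edit distance 1")
    return INDEL


@dataclass
class CSRGraph:
    """Isotype-subclass co-occurrence graph.

    Nodes are subclasses, edges carry the number of clonotypes observed in
    both subclasses of the pair plus that pair's share of all co-occurring
    clonotypes. ``total`` is the number of co-occurring clonotypes.
    """

    graph: nx.Graph
    total: int

    def pair_count(self, pair: tuple[str, str]) -> int:
        a, b = pair
        if self.graph.has_edge(a, b):
            return int(self.graph.edges[a, b]["count"])
        return 0

    def pair_ratio(self, pair: tuple[str, str]) -> float:
        if self.total == 0:
            return 0.0
        return self.pair_count(pair) / self.total

    def subclass_count(self, subclass: str) -> int:
        """Co-occurring clonotypes involving one subclass (alternative
        denominator for per-pair shares)."""
        if subclass not in self.graph:
            return 0
        return sum(int(d["count"]) for _, _, d in self.graph.edges(subclass, data=True))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subclass_a": min(a, b),
                "subclass_b": max(a, b),
                "count": int(d["count"]),
                "ratio": d["count"] / self.total if self.total else 0.0,
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["subclass_a", "subclass_b", "count", "ratio"])
        return df.sort_values(
            ["count", "subclass_a", "subclass_b"], ascending=[False, True, True]
        ).reset_index(drop=True)


def csr_cooccurrence(rep: Repertoire) -> CSRGraph:
    """Build the subclass co-occurrence graph from multi-subclass clonotypes.

    Rows sharing identical CDR3nt + resolved V + resolved J are merged first;
    a merged clonotype whose constant-gene calls resolve to exactly two
    distinct subclasses contributes one count to that unordered pair.
    Clonotypes with one or >= 3 subclasses contribute nothing. Invariant
    under row order.
    """
    _require_qc(rep)
    union: dict[tuple[str | None, str | None, str], set[str]] = {}
    for c in rep.clones:
        v = resolve_gene_call(c.v_call, level="gene")
        j = resolve_gene_call(c.j_call, level="gene")
        subs = {strip_allele(x) for x in c.c_call} & set(SUBCLASSES)
        union.setdefault((v, j, c.cdr3_nt), set()).update(subs)
    counts: dict[tuple[str, str], int] = {}
    for subs in union.values():
        if len(subs) == 2:
            pair = tuple(sorted(subs))
            counts[pair] = counts.get(pair, 0) + 1
    graph = nx.Graph()
    total = sum(counts.values())
    for (a, b), n in sorted(counts.items()):
        graph.add_edge(a, b, count=n, ratio=n / total if total else 0.0)
    return CSRGraph(graph=graph, total=total)


def csr_ratio(rep_or_graph: Repertoire | CSRGraph, pair: tuple[str, str]) -> float:
    """One pair's share of all co-occurrence counts (0 when the graph is empty)."""
    graph = (
        rep_or_graph
        if isinstance(rep_or_graph, CSRGraph)
        else csr_cooccurrence(rep_or_graph)
    )
    return graph.pair_ratio(pair)


def lineages_to_frame(lineages: list[Lineage]) -> pd.DataFrame:
    """Flatten lineages to a tidy table (one row per member clonotype)."""
    rows = []
    for lid, lin in enumerate(lineages):
        rows.append(
            {
                "lineage_id": lid,
                "role": "root",
                "cdr3_nt": lin.root.cdr3_nt,
                "v_gene": lin.v_gene,
                "j_gene": lin.j_gene,
                "clone_count": lin.root.clone_count,
                "mutation_class": "",
            }
        )
        for v in lin.variants:
            rows.append(
                {
                    "lineage_id": lid,
                    "role": "variant",
                    "cdr3_nt": v.cdr3_nt,
                    "v_gene": lin.v_gene,
                    "j_gene": lin.j_gene,
                    "clone_count": v.clone_count,
                    "mutation_class": classify_mutation(lin.root.cdr3_nt, v.cdr3_nt),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage_id", "role", "cdr3_nt", "v_gene", "j_gene",
            "clone_count", "mutation_class",
        ],
    )
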