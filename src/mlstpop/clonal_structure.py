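"""Clonal complexes (eBURST-style) and minimum spanning trees over STs.

Clonal complexes (CCs) group sequence types connected through single-locus
variant (SLV) links: with L loci the default rule links STs sharing at
least L-1 alleles.  Each CC's founder is predicted as the member with the
most SLV partners (ties: more DLVs, more isolates, smaller ST number),
mirroring the eBURST heuristic that the ancestral genotype accumulates the
most one-step descendants.

The minimum spanning tree is built on the complete graph of STs weighted by
allelic distance, with deterministic goeBURST-inspired tie-breaking among
equal-weight edges (endpoint SLV counts, then isolate counts, then ST
numbers), since the tie-breaks of the commercial tool that popularized
MST-of-profiles rendering are unpublished.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .allele_typing import AllelicProfile, ProfileTable
from .seqdata_io import MLSTError


def allelic_distance(a: AllelicProfile, b: AllelicProfile) -> int:
    """Number of loci at which two allelic profiles differ."""
    if len(a) != len(b):
        raise MLSTError(f"profile length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class CloneComplex:
    """A group of >= 2 STs connected through SLV links."""

    id: str
    member_sts: list[int]
    founder_st: int
    slv_counts: dict[int, int] = field(default_factory=dict)
    dlv_counts: dict[int, int] = field(default_factory=dict)
    n_isolates: int = 0
    founder_tiebreak: str = ""

    def __post_init__(self) -> None:
        if len(self.member_sts) < 2:
            raise MLSTError("a clonal complex needs >= 2 member STs")
        if self.founder_st not in self.member_sts:
            raise MLSTError("founder must be a member")


@dataclass
class SpanningTree:
    """Minimum spanning tree over ST allelic profiles."""

    nodes: dict[int, dict]          # ST -> {"size": int, "source": str}
    edges: list[tuple[int, int, int]]  # (st_a, st_b, allelic distance)
    total_weight: int

    def edge_classes(self) -> list[tuple[int, int, int, str]]:
        """Annotate edges with the conventional rendering class."""
        classes = {1: "bold", 2: "thin", 3: "dotted"}
        return [
            (a, b, d, classes.get(d, "suppressed")) for a, b, d in self.edges
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for st, attrs in self.nodes.items():
            g.add_node(st, **attrs)
        for a, b, d in self.edges:
            g.add_edge(a, b, weight=d)
        return g


def _variant_counts(table: ProfileTable) -> tuple[dict[int, int], dict[int, int]]:
    """SLV and DLV partner counts for every ST over the whole table."""
    sts = sorted(table.st_profiles)
    slv = {st: 0 for st in sts}
    dlv = {st: 0 for st in sts}
    for i, a in enumerate(sts):
        for b in sts[i + 1 :]:
            d = allelic_distance(table.st_profiles[a], table.st_profiles[b])
            if d == 1:
                slv[a] += 1
                slv[b] += 1
            elif d == 2:
                dlv[a] += 1
                dlv[b] += 1
    return slv, dlv


def predict_founder(
    members: list[int], table: ProfileTable
) -> tuple[int, str]:
    """Predict the founder ST of one complex.

    The founder maximizes the SLV count *within the complex*; ties fall
    through DLV count, isolate count, then smallest ST number.  Returns the
    founder and a trace naming the tie-break level that decided it.
    """
    if len(members) < 2:
        raise MLSTError("founder prediction needs >= 2 members")
    members = sorted(members)
    slv = {st: 0 for st in members}
    dlv = {st: 0 for st in members}
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            d = allelic_distance(table.st_profiles[a], table.st_profiles[b])
            if d == 1:
                slv[a] += 1
                slv[b] += 1
            elif d == 2:
                dlv[a] += 1
                dlv[b] += 1
    stages = [
        ("slv", lambda st: slv[st]),
        ("dlv", lambda st: dlv[st]),
        ("isolate_count", lambda st: table.st_size(st)),
    ]
    cands = list(members)
    for name, key in stages:
        best = max(key(st) for st in cands)
        cands = [st for st in cands if key(st) == best]
        if len(cands) == 1:
            return cands[0], name
    return min(cands), "st_number"


def find_clonal_complexes(
    table: ProfileTable, group_threshold: int | None = None
) -> tuple[list[CloneComplex], list[int]]:
    """Partition STs into clonal complexes and singletons.

    STs sharing >= ``group_threshold`` alleles (default L-1, the SLV rule)
    are linked; connected components with >= 2 members become CCs labelled
    CC1, CC2, ... by descending isolate count (ties: more STs, then smaller
    minimum ST number).  Remaining STs are returned as singletons.
    """
    L = table.n_loci
    if group_threshold is None:
        group_threshold = L - 1
    if not 1 <= group_threshold <= L:
        raise MLSTError(f"group_threshold must be in [1, {L}]")
    max_dist = L - group_threshold
    sts = sorted(table.st_profiles)
    g = nx.Graph()
    g.add_nodes_from(sts)
    for i, a in enumerate(sts):
        for b in sts[i + 1 :]:
            if allelic_distance(table.st_profiles[a], table.st_profiles[b]) <= max_dist:
                g.add_edge(a, b)
    slv_all, dlv_all = _variant_counts(table)
    groups = []
    singletons: list[int] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            singletons.append(comp[0])
        else:
            groups.append(comp)
    groups.sort(
        key=lambda ms: (
            -sum(table.st_size(st) for st in ms),
            -len(ms),
            min(ms),
        )
    )
    complexes: list[CloneComplex] = []
    for rank, members in enumerate(groups, start=1):
        founder, trace = predict_founder(members, table)
        complexes.append(
            CloneComplex(
                id=f"CC{rank}",
                member_sts=members,
                founder_st=founder,
                slv_counts={st: slv_all[st] for st in members},
                dlv_counts={st: dlv_all[st] for st in members},
                n_isolates=sum(table.st_size(st) for st in members),
                founder_tiebreak=trace,
            )
        )
    return complexes, sorted(singletons)


def cc_partition(
    complexes: list[CloneComplex], singletons: list[int]
) -> list[frozenset[int]]:
    """The ST partition induced by CCs plus singleton STs."""
    parts = [frozenset(cc.member_sts) for cc in complexes]
    parts += [frozenset([st]) for st in singletons]
    return sorted(parts, key=lambda s: min(s))


def build_mst(table: ProfileTable, dominant_source=None) -> SpanningTree:
    """Minimum spanning tree of the complete allelic-distance graph on STs.

    Kruskal scan over edges sorted by (distance, tie-key); the tie-key
    prefers edges whose endpoints have larger summed SLV counts, then
    larger summed isolate counts, then the lexicographically smaller ST
    pair — fully deterministic.
    """
    sts = sorted(table.st_profiles)
    slv, _ = _variant_counts(table)
    nodes = {
        st: {
            "size": table.st_size(st),
            "source": (dominant_source or {}).get(st, ""),
        }
        for st in sts
    }
    if len(sts) == 1:
        import logging

        logging.getLogger(__name__).warning("single ST: degenerate MST")
        return SpanningTree(nodes, [], 0)
    edges = []
    for i, a in enumerate(sts):
        for b in sts[i + 1 :]:
            d = allelic_distance(table.st_profiles[a], table.st_profiles[b])
            tie = (
                -(slv[a] + slv[b]),
                -(table.st_size(a) + table.st_size(b)),
                (a, b),
            )
            edges.append((d, tie, a, b))
    edges.sort(key=lambda e: (e[0], e[1]))
    parent = {st: st for st in sts}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[int, int, int]] = []
    total = 0
    for d, _, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b, d))
            total += d
            if len(chosen) == len(sts) - 1:
                break
    return SpanningTree(nodes, chosen, total)


def write_cc_table(path, complexes: list[CloneComplex], singletons: list[int]) -> None:
    """Tab-separated ``ST<TAB>complex<TAB>founder_flag`` assignment table."""
    with open(path, "w") as fh:
        fh.write("ST\tcomplex\tfounder_flag\n")
        rows = []
        for cc in complexes:
            for st in cc.member_sts:
                rows.append((st, cc.id, int(st == cc.founder_st)))
        for st in singletons:
            rows.append((st, "singleton", 0))
        for st, label, flag in sorted(rows):
            fh.write(f"{st}\t{label}\t{flag}\n")


def write_mst_graphml(path, tree: SpanningTree) -> None:
    nx.write_graphml(tree.to_networkx(), path)


def write_mst_dot(path, tree: SpanningTree) -> None:
    lines = ["graph MST {"]
    for st, attrs in tree.nodes.items():
        lines.append(f'  {st} [size={attrs["size"]}];')
    style = {"bold": "bold", "thin": "solid", "dotted": "dotted", "suppressed": "invis"}
    for a, b, d, cls in tree.edge_classes():
        lines.append(f'  {a} -- {b} [label={d}, style={style[cls]}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
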