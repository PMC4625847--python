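"""Distance-based phylogenetics on concatenated ST sequences.

Implements the Kimura two-parameter (K2P) distance, Saitou-Nei
neighbour-joining with column-bootstrap support, and Bandelt-Dress split
decomposition.  K2P corrects transitions (A<->G, C<->T) and transversions
separately; split decomposition extracts all weighted bipartitions
(d-splits, isolation index alpha > 0) from a distance matrix — incompatible
splits render as network boxes, the classic signature of recombination in
a clonal framework.

Sites containing 'N' are excluded pairwise, consistent with the diversity
statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .seqdata_io import MLSTError

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

# isolation indices below this are treated as zero (floating-point guard)
_ALPHA_TOL = 1e-9


class SaturationError(MLSTError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise MLSTError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise MLSTError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise MLSTError("nonzero diagonal")
        if np.any(self.d < 0):
            raise MLSTError("negative distances")

    def __len__(self) -> int:
        return len(self.taxa)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for name, row in zip(self.taxa, self.d):
                fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def k2p_distance(s1: str, s2: str) -> float:
    """Kimura two-parameter distance between two equal-length sequences.

    With P and Q the transition and transversion proportions over mutually
    non-N sites: d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).
    """
    if len(s1) != len(s2):
        raise MLSTError("unequal sequence lengths")
    comparable = transitions = transversions = 0
    for x, y in zip(s1, s2):
        if x == "N" or y == "N":
            continue
        comparable += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if comparable == 0:
        raise MLSTError("no mutually non-N site")
    P, Q = transitions / comparable, transversions / comparable
    arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(f"saturated pair (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def k2p_matrix(alignment) -> DistanceMatrix:
    """Pairwise K2P matrix over a ConcatenatedAlignment or (ids, seqs)."""
    if hasattr(alignment, "ids"):
        ids, seqs = list(alignment.ids), list(alignment.matrix)
    else:
        ids, seqs = list(alignment[0]), list(alignment[1])
    mat = _encode(seqs)
    A, G, C, T, N = (ord(c) for c in "AGCTN")
    n = len(ids)
    d = np.zeros((n, n))
    saturated = []
    purine = (mat == A) | (mat == G)
    ok = mat != N
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise MLSTError(f"no comparable site for pair ({ids[i]}, {ids[j]})")
            diff = (mat[i] != mat[j]) & both
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            P, Q = ts / comparable, tv / comparable
            arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if arg1 <= 0 or arg2 <= 0:
                saturated.append((ids[i], ids[j]))
                continue
            d[i, j] = d[j, i] = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    if saturated:
        raise SaturationError(f"saturated pairs: {saturated}")
    return DistanceMatrix(ids, d)


class _Node:
    __slots__ = ("label", "children", "length")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[_Node] = []  # (child.length is the branch above it)
        self.length = 0.0


@dataclass
class PhyloTree:
    """Unrooted tree (rooted representation at a trifurcation).

    ``support`` maps canonical bipartitions (frozenset of leaf labels on
    the side not containing the alphabetically first taxon) to bootstrap
    percentages in [0, 100].
    """

    root: _Node
    taxa: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: _Node) -> None:
            if not node.children:
                out.append(node.label)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalized."""
        ref = min(self.taxa)
        all_taxa = set(self.taxa)
        parts: set[frozenset] = set()

        def walk(node: _Node) -> set:
            if not node.children:
                return {node.label}
            below = set()
            for c in node.children:
                sub = walk(c)
                if 2 <= len(sub) <= len(all_taxa) - 2:
                    side = sub if ref not in sub else all_taxa - sub
                    parts.add(frozenset(side))
                below |= sub
            return below

        walk(self.root)
        return parts

    def to_newick(self, include_support: bool = False) -> str:
        ref = min(self.taxa)
        all_taxa = set(self.taxa)

        def walk(node: _Node) -> tuple[str, set]:
            if not node.children:
                return f"{node.label}:{node.length:.6f}", {node.label}
            parts, below = [], set()
            for c in node.children:
                s, sub = walk(c)
                parts.append(s)
                below |= sub
            label = ""
            if include_support and 2 <= len(below) <= len(all_taxa) - 2:
                side = below if ref not in below else all_taxa - below
                sup = self.support.get(frozenset(side))
                if sup is not None:
                    label = f"{sup:.0f}"
            return f"({','.join(parts)}){label}:{node.length:.6f}", below

        inner = ",".join(walk(c)[0] for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path, include_support: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_support) + "\n")


def neighbour_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Pair selection uses the standard Q criterion; ties are broken by the
    smallest taxon-index pair (indices follow node creation order).
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling branch.
    """
    n = len(dm)
    if n < 2:
        raise MLSTError("need >= 2 taxa")
    nodes: list[_Node] = []
    for name in dm.taxa:
        nodes.append(_Node(name))
    if n == 2:
        half = dm.d[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        root = _Node()
        root.children = nodes
        return PhyloTree(root, list(dm.taxa))
    active = list(range(n))
    d = {
        (i, j): float(dm.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = _Node()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = li, lj
        parent.children = [ci, cj]
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
    # join the final three nodes at an unrooted trifurcation
    i, j, k = active
    li = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
    lj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
    lk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
    root = _Node()
    for idx, ln in zip((i, j, k), (li, lj, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.children.append(nodes[idx])
    return PhyloTree(root, list(dm.taxa))


def bootstrap_support(
    alignment, n_reps: int = 1000, seed: int | None = None
) -> PhyloTree:
    """NJ tree with column-bootstrap branch support.

    Columns are resampled with replacement; each replicate is rebuilt with
    K2P + NJ and support is the percentage of replicates containing each
    internal bipartition of the tree built on the original alignment.
    Taxa are canonically sorted before resampling so support values are
    invariant to input taxon order for a given seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if hasattr(alignment, "ids"):
        ids, seqs = list(alignment.ids), list(alignment.matrix)
    else:
        ids, seqs = list(alignment[0]), list(alignment[1])
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    ids = [ids[i] for i in order]
    seqs = [seqs[i] for i in order]
    tree = neighbour_joining(k2p_matrix((ids, seqs)))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    mat = _encode(seqs)
    L = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        res = mat[:, cols]
        rows = ["".join(map(chr, row)) for row in res]
        rep_tree = neighbour_joining(k2p_matrix((ids, rows)))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    tree.support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree


# --- split decomposition -------------------------------------------------


@dataclass
class SplitSystem:
    """Weighted d-splits of a distance matrix.

    Splits are stored as (frozenset of taxon labels on one side, alpha).
    ``fit`` is the percentage of the total pairwise distance represented
    by the split metric (100 for additive, tree-like matrices).
    """

    taxa: list[str]
    splits: list[tuple[frozenset, float]]
    fit: float = 0.0

    def nontrivial(self) -> list[tuple[frozenset, float]]:
        n = len(self.taxa)
        return [
            (s, a) for s, a in self.splits if 2 <= len(s) <= n - 2
        ]

    def write_nexus(self, path) -> None:
        idx = {t: i + 1 for i, t in enumerate(self.taxa)}
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(self.taxa)};\n  TAXLABELS\n")
            for t in self.taxa:
                fh.write(f"    '{t}'\n")
            fh.write("  ;\nEND;\n\nBEGIN SPLITS;\n")
            fh.write(
                f"  DIMENSIONS NTAX={len(self.taxa)} NSPLITS={len(self.splits)};\n"
            )
            fh.write("  FORMAT LABELS=NO WEIGHTS=YES;\n  MATRIX\n")
            for side, alpha in self.splits:
                members = sorted(idx[t] for t in side)
                fh.write(
                    f"    {alpha:.6f}\t" + " ".join(map(str, members)) + ",\n"
                )
            fh.write("  ;\nEND;\n")


def isolation_index(dm: DistanceMatrix, side_a, side_b=None) -> float:
    """Isolation index alpha of a bipartition A|B.

    alpha = (1/2) min over {i,j} in A, {k,l} in B of
    [max(d(i,k)+d(j,l), d(i,l)+d(j,k), d(i,j)+d(k,l)) - d(i,j) - d(k,l)],
    with i=j allowed (singleton sides).  Positive alpha marks a d-split;
    for a tree metric the alpha of a tree edge equals its branch length.
    """
    index = {t: i for i, t in enumerate(dm.taxa)}
    A = sorted(index[t] for t in side_a)
    if side_b is None:
        B = sorted(set(range(len(dm.taxa))) - set(A))
    else:
        B = sorted(index[t] for t in side_b)
    if not A or not B or set(A) & set(B) or len(A) + len(B) != len(dm.taxa):
        raise MLSTError("not a proper bipartition")
    d = dm.d
    best = math.inf
    for i, j in itertools.combinations_with_replacement(A, 2):
        dij = d[i, j]
        for k, l in itertools.combinations_with_replacement(B, 2):
            dkl = d[k, l]
            m = max(d[i, k] + d[j, l], d[i, l] + d[j, k], dij + dkl)
            beta = 0.5 * (m - dij - dkl)
            if beta < best:
                best = beta
                if best <= 0:
                    return float(best)
    return float(best)


def _split_metric_total(dm: DistanceMatrix, splits) -> float:
    index = {t: i for i, t in enumerate(dm.taxa)}
    n = len(dm.taxa)
    total = 0.0
    for side, alpha in splits:
        k = len({index[t] for t in side})
        total += alpha * k * (n - k)
    return total


def split_decomposition(dm: DistanceMatrix, method: str = "incremental") -> SplitSystem:
    """All d-splits (alpha > 0) of a distance matrix.

    ``incremental`` adds taxa one at a time, extending every current
    d-split both ways plus the new trivial split and keeping those with
    positive isolation index (valid because restrictions of d-splits are
    d-splits).  ``exhaustive`` checks every bipartition (oracle mode,
    n <= 12).
    """
    taxa = list(dm.taxa)
    n = len(taxa)
    if method == "exhaustive":
        if n > 12:
            raise MLSTError("exhaustive mode limited to 12 taxa")
        splits = []
        others = taxa[1:]
        for r in range(len(others) + 1):
            for combo in itertools.combinations(others, r):
                side = frozenset(combo) | {taxa[0]}
                if len(side) == n:
                    continue
                alpha = isolation_index(dm, side)
                if alpha > _ALPHA_TOL:
                    splits.append((side, alpha))
    elif method == "incremental":
        index = {t: i for i, t in enumerate(taxa)}

        def sub_matrix(labels: list[str]) -> DistanceMatrix:
            ids = [index[t] for t in labels]
            return DistanceMatrix(labels, dm.d[np.ix_(ids, ids)])

        current: list[frozenset] = [frozenset([taxa[0]])]
        for m in range(2, n + 1):
            sub_taxa = taxa[:m]
            new_taxon = taxa[m - 1]
            sub = sub_matrix(sub_taxa)
            candidates = {frozenset([new_taxon]), frozenset(sub_taxa[:-1])}
            for side in current:
                candidates.add(side)
                candidates.add(side | {new_taxon})
            current = []
            for side in candidates:
                if not 0 < len(side) < m:
                    continue
                if isolation_index(sub, side) > -_ALPHA_TOL:
                    current.append(side)
        # final filter on the full matrix, canonical side, same call as
        # exhaustive mode so borderline alphas resolve identically
        splits = []
        for side in current:
            canon = side if taxa[0] in side else frozenset(set(taxa) - side)
            alpha = isolation_index(dm, canon)
            if alpha > _ALPHA_TOL:
                splits.append((canon, alpha))
    else:
        raise ValueError(f"unknown method {method!r}")
    # deduplicate complements and sort deterministically
    seen: dict[frozenset, float] = {}
    for side, alpha in splits:
        canon = side if taxa[0] in side else frozenset(set(taxa) - side)
        seen[canon] = alpha
    ordered = sorted(seen.items(), key=lambda sa: (len(sa[0]), sorted(sa[0])))
    total_d = float(dm.d[np.triu_indices(n, k=1)].sum())
    system = SplitSystem(taxa, ordered)
    if total_d > 0:
        system.fit = 100.0 * _split_metric_total(dm, ordered) / total_d
    return system
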