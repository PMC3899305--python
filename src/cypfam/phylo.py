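"""Minimum-evolution phylogenetics for P450 family alignments.

Pipeline: Poisson-corrected pairwise distances from a protein alignment,
a neighbor-joining starting tree, ordinary-least-squares (OLS) branch
lengths on a fixed topology, and a minimum-evolution search by
close-neighbor-interchange (CNI) over nearest-neighbor-interchange (NNI)
neighborhoods.  The ME criterion scores a topology by the sum of its
OLS-fitted branch lengths (negatives included) and keeps the topology
with the smallest sum.

Trees are unrooted and binary: ``n`` leaves, ``n - 2`` internal nodes and
``2n - 3`` edges (for ``n >= 3``).  Leaves are taxon label strings,
internal nodes are negative integers.  An exhaustive enumerator over all
unrooted binary topologies (up to 8 taxa, 10395 topologies) serves as an
independent optimum oracle for the heuristic search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

from Bio import SeqIO

GAP = "-"

#: p-distance above which a pair is treated as saturated
SATURATION_P = 0.95
#: minimum ME-score improvement accepted by the CNI search
CNI_TOL = 1e-12


# ---------------------------------------------------------------------------
# alignment + distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """A gapped protein alignment: unique taxa, equal-length rows."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.description.split()[0])
            rows.append(str(rec.seq).upper())
        return cls(taxa=tuple(taxa), rows=tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("non-zero diagonal")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def reordered(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(tuple(taxa), self.values[np.ix_(idx, idx)])


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing residues among pairwise-comparable columns.

    Columns with a gap in either row are ignored (pairwise deletion; for
    complete deletion remove globally-gapped columns first, as
    :func:`distance_matrix` does).  Raises ``ValueError`` when no column
    is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal lengths")
    compared = diffs = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable columns between rows")
    return diffs / compared


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance ``d = -ln(1 - p)`` (substitutions/site).

    Raises ``ValueError`` for saturated pairs (``p >= 1``); the matrix
    builder substitutes a configured ceiling instead.
    """
    if not 0.0 <= p:
        raise ValueError(f"p-distance must be >= 0: {p}")
    if p >= 1.0:
        raise ValueError("saturated pair: p >= 1 has no Poisson correction")
    return -math.log1p(-p)


def distance_matrix(
    aln: Alignment,
    deletion: str = "complete",
    correction: str = "poisson",
    saturation_p: float = SATURATION_P,
) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``deletion='complete'`` removes every column gapped in any taxon
    before comparison (the default, matching MEGA); ``'pairwise'`` drops
    gapped columns per pair.  ``correction='poisson'`` applies
    ``-ln(1-p)``; ``'p'`` returns raw p-distances.  p-distances above
    ``saturation_p`` are capped at that value with a warning so the
    corrected matrix stays finite.
    """
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode: {deletion!r}")
    if correction not in ("poisson", "p"):
        raise ValueError(f"unknown correction: {correction!r}")
    rows = list(aln.rows)
    if deletion == "complete":
        keep = [
            c for c in range(aln.n_columns) if all(r[c] != GAP for r in rows)
        ]
        if not keep and aln.n_columns:
            raise ValueError("complete deletion removed every column")
        rows = ["".join(r[c] for c in keep) for r in rows]
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        p = p_distance(rows[i], rows[j])
        if correction == "poisson":
            if p > saturation_p:
                warnings.warn(
                    f"saturated pair ({aln.taxa[i]}, {aln.taxa[j]}): "
                    f"p={p:.3f} capped at {saturation_p}",
                    stacklevel=2,
                )
                p = saturation_p
            val = poisson_distance(p)
        else:
            val = p
        d[i, j] = d[j, i] = val
    return DistanceMatrix(aln.taxa, d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class Tree:
    """Unrooted tree over taxon-labelled leaves.

    ``graph`` is a :class:`networkx.Graph` whose leaf nodes are the taxon
    strings and whose internal nodes are negative ints; edges carry a
    ``length`` attribute (``None`` until fitted).
    """

    def __init__(self, graph: nx.Graph, taxa: Sequence[str]):
        self.graph = graph
        self.taxa = tuple(taxa)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def copy(self) -> "Tree":
        return Tree(self.graph.copy(), self.taxa)

    def branch_lengths(self) -> dict[frozenset, float]:
        return {
            frozenset((u, v)): data["length"]
            for u, v, data in self.graph.edges(data=True)
        }

    @property
    def me_score(self) -> float:
        """Sum of branch lengths (negatives included)."""
        total = 0.0
        for _, _, data in self.graph.edges(data=True):
            if data.get("length") is None:
                raise ValueError("tree has unfitted branch lengths")
            total += data["length"]
        return total

    # -- topology -----------------------------------------------------------

    def splits(self, nontrivial: bool = True) -> frozenset[frozenset]:
        """Bipartitions induced by the edges, as canonical taxon sets.

        Each edge is represented by the side *not* containing the first
        taxon (a rooting-free canonical form).  ``nontrivial`` drops
        leaf-pendant edges.
        """
        anchor = self.taxa[0]
        out = set()
        for u, v in self.graph.edges():
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {n for n in nx.node_connected_component(g, u) if not _is_internal(n)}
            if anchor in side:
                side = set(self.taxa) - side
            if nontrivial and not (2 <= len(side) <= self.n_taxa - 2):
                continue
            out.add(frozenset(side))
        return frozenset(out)

    def split_lengths(self) -> dict[frozenset, float]:
        """Branch length per edge keyed by the edge's canonical bipartition.

        Trivial (leaf) splits are included; keys are comparable across
        trees with different internal node ids.
        """
        anchor = self.taxa[0]
        out: dict[frozenset, float] = {}
        for u, v in self.graph.edges():
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {n for n in nx.node_connected_component(g, u) if not _is_internal(n)}
            if anchor in side:
                side = set(self.taxa) - side
            out[frozenset(side)] = self.graph.edges[u, v]["length"]
        return out

    def same_topology(self, other: "Tree") -> bool:
        return set(self.taxa) == set(other.taxa) and self.splits() == other.splits()

    def path_length(self, a: str, b: str) -> float:
        path = nx.shortest_path(self.graph, a, b)
        return sum(
            self.graph.edges[u, v]["length"] for u, v in zip(path, path[1:])
        )

    # -- newick -------------------------------------------------------------

    def to_newick(self, clamp_negative: bool = True, fmt: str = "%.6g") -> str:
        """Newick with branch lengths (negatives clamped to 0 by default).

        The unrooted tree is written as a basal multifurcation at the
        internal node adjacent to the alphabetically first taxon; sibling
        order is by smallest contained taxon, so the string is a
        deterministic function of the topology.
        """

        def blen(u, v) -> str:
            x = self.graph.edges[u, v]["length"]
            if x is None:
                return ""
            if clamp_negative and x < 0:
                x = 0.0
            return ":" + (fmt % x)

        def subtree_min(node, parent) -> str:
            if not _is_internal(node):
                return node
            return min(
                subtree_min(c, node) for c in self.graph.neighbors(node) if c != parent
            )

        def render(node, parent) -> str:
            if not _is_internal(node):
                return node + blen(node, parent)
            children = sorted(
                (c for c in self.graph.neighbors(node) if c != parent),
                key=lambda c: subtree_min(c, node),
            )
            inner = ",".join(render(c, node) for c in children)
            return f"({inner})" + (blen(node, parent) if parent is not None else "")

        if self.n_taxa == 2:
            a, b = sorted(self.taxa)
            d = self.graph.edges[a, b].get("length")
            if d is None:
                return f"({a},{b});"
            half = fmt % (max(d, 0.0) / 2 if clamp_negative else d / 2)
            return f"({a}:{half},{b}:{half});"
        first = min(self.taxa)
        root = next(iter(self.graph.neighbors(first)))
        return render(root, None) + ";"


def _is_internal(node) -> bool:
    return isinstance(node, int)


class _NodeIds:
    """Deterministic supply of fresh internal-node ids (negative ints)."""

    def __init__(self, graph: nx.Graph | None = None):
        used = [n for n in graph.nodes if _is_internal(n)] if graph is not None else []
        self._next = min(used) - 1 if used else -1

    def new(self) -> int:
        nid = self._next
        self._next -= 1
        return nid


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Agglomerates on the Q-criterion; ties are broken by the smallest
    ``(i, j)`` index pair in the current working order (documented for
    reproducibility).  ``n = 2`` yields a single edge; ``n = 3`` the
    unique star with closed-form branch lengths.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    g = nx.Graph()
    ids = _NodeIds()
    if n == 2:
        a, b = dm.taxa
        g.add_edge(a, b, length=float(dm.values[0, 1]))
        return Tree(g, dm.taxa)

    nodes: list = list(dm.taxa)
    D = dm.values.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        sums = D.sum(axis=1)
        Q = (m - 2) * D - sums[:, None] - sums[None, :]
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or Q[i, j] < best[0]:
                    best = (Q[i, j], i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        u = ids.new()
        g.add_edge(nodes[i], u, length=float(li))
        g.add_edge(nodes[j], u, length=float(lj))
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        dk = dnew[keep]
        D[i, :] = dk
        D[:, i] = dk
        D[i, i] = 0.0
        nodes[i] = u
        del nodes[j]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = ids.new()
    g.add_edge(a, center, length=float((dab + dac - dbc) / 2))
    g.add_edge(b, center, length=float((dab + dbc - dac) / 2))
    g.add_edge(c, center, length=float((dac + dbc - dab) / 2))
    return Tree(g, dm.taxa)


# ---------------------------------------------------------------------------
# OLS branch lengths + ME score
# ---------------------------------------------------------------------------


def _design_matrix(tree: Tree) -> tuple[np.ndarray, list[frozenset]]:
    """Pairwise path-incidence design matrix for OLS branch fitting.

    Row order follows ``combinations(tree.taxa, 2)``; column order follows
    a sorted edge list (stable across topologically identical graphs).
    """
    edges = sorted(tree.graph.edges(), key=lambda e: sorted(map(str, e)))
    eidx = {frozenset(e): k for k, e in enumerate(edges)}
    pairs = list(combinations(tree.taxa, 2))
    A = np.zeros((len(pairs), len(edges)))
    paths = {t: nx.single_source_shortest_path(tree.graph, t) for t in tree.taxa}
    for r, (a, b) in enumerate(pairs):
        path = paths[a][b]
        for u, v in zip(path, path[1:]):
            A[r, eidx[frozenset((u, v))]] = 1.0
    return A, [frozenset(e) for e in edges]


@dataclass
class OlsFit:
    """OLS branch-length fit of a topology to a distance matrix."""

    tree: Tree
    ssq: float
    me_score: float


def ols_branch_lengths(tree: Tree, dm: DistanceMatrix) -> OlsFit:
    """Fit branch lengths minimising sum (d_ij - path_ij)^2.

    Returns a new tree carrying the fitted lengths together with the
    residual sum of squares and the ME score (raw sum of lengths,
    negatives included).
    """
    if set(tree.taxa) != set(dm.taxa):
        raise ValueError("tree and distance matrix cover different taxa")
    dm = dm.reordered(tree.taxa)
    A, edges = _design_matrix(tree)
    d = np.array(
        [dm.values[i, j] for i, j in combinations(range(dm.n), 2)]
    )
    x, _, rank, _ = np.linalg.lstsq(A, d, rcond=None)
    if rank < A.shape[1]:
        raise ValueError("degenerate topology: singular OLS design")
    resid = A @ x - d
    fitted = tree.copy()
    for e, length in zip(edges, x):
        u, v = tuple(e)
        fitted.graph.edges[u, v]["length"] = float(length)
    return OlsFit(tree=fitted, ssq=float(resid @ resid), me_score=float(x.sum()))


# ---------------------------------------------------------------------------
# NNI neighborhood + CNI search
# ---------------------------------------------------------------------------


def nni_neighbors(tree: Tree) -> list[Tree]:
    """All topologies one nearest-neighbor interchange away.

    Each internal edge yields two alternative topologies; enumeration
    order is deterministic.  Branch lengths are dropped (refit after).
    """
    out: list[Tree] = []
    internal_edges = sorted(
        (
            (u, v)
            for u, v in tree.graph.edges()
            if _is_internal(u) and _is_internal(v)
        ),
        key=lambda e: sorted(map(str, e)),
    )
    for u, v in internal_edges:
        a, b = sorted((x for x in tree.graph.neighbors(u) if x != v), key=str)
        c, d = sorted((x for x in tree.graph.neighbors(v) if x != u), key=str)
        for swap_from, swap_to in ((b, c), (b, d)):
            g = nx.Graph()
            g.add_nodes_from(tree.graph.nodes)
            g.add_edges_from(tree.graph.edges)
            g.remove_edge(u, swap_from)
            g.remove_edge(v, swap_to)
            g.add_edge(u, swap_to)
            g.add_edge(v, swap_from)
            for e in g.edges:
                g.edges[e]["length"] = None
            out.append(Tree(g, tree.taxa))
    return out


@dataclass
class CniResult:
    """Outcome of a CNI search: final fitted tree and score trajectory."""

    tree: Tree
    ssq: float
    me_score: float
    trajectory: list[float] = field(default_factory=list)
    n_iterations: int = 0


def cni_search(
    start: Tree,
    dm: DistanceMatrix,
    level: int = 1,
    tol: float = CNI_TOL,
) -> CniResult:
    """Minimum-evolution search by close-neighbor interchange.

    Iterated best-improvement local search: at search level 1 the
    neighborhood is all topologies one NNI away; level ``k`` explores
    topologies within ``k`` NNI moves.  A neighbor is accepted only when
    its ME score is strictly smaller (by more than ``tol``); the search
    stops at a local optimum, so the result never scores worse than the
    start.
    """
    if level < 1:
        raise ValueError("search level must be >= 1")
    current = ols_branch_lengths(start, dm)
    trajectory = [current.me_score]
    iterations = 0
    while True:
        candidates = _nni_neighborhood(current.tree, level)
        best: OlsFit | None = None
        for cand in candidates:
            fit = ols_branch_lengths(cand, dm)
            if best is None or fit.me_score < best.me_score:
                best = fit
        if best is None or best.me_score >= current.me_score - tol:
            break
        current = best
        trajectory.append(current.me_score)
        iterations += 1
    return CniResult(
        tree=current.tree,
        ssq=current.ssq,
        me_score=current.me_score,
        trajectory=trajectory,
        n_iterations=iterations,
    )


def _nni_neighborhood(tree: Tree, level: int) -> list[Tree]:
    if level == 1:
        # the 2(n-3) single-NNI neighbors are pairwise distinct topologies,
        # so the split-set dedup below is only needed for deeper levels
        return nni_neighbors(tree)
    frontier = [tree]
    seen = {tree.splits()}
    out: list[Tree] = []
    for _ in range(level):
        nxt: list[Tree] = []
        for t in frontier:
            for nb in nni_neighbors(t):
                key = nb.splits()
                if key not in seen:
                    seen.add(key)
                    out.append(nb)
                    nxt.append(nb)
        frontier = nxt
    return out


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle)
# ---------------------------------------------------------------------------

MAX_EXHAUSTIVE_TAXA = 8


@lru_cache(maxsize=8)
def _topology_bank(taxa: tuple[str, ...]) -> tuple[tuple[tuple, ...], ...]:
    """Edge lists of every unrooted binary topology over ``taxa``.

    Built by inserting each taxon in turn onto every edge of every
    partial topology ((2n-5)!! trees); cached because oracles evaluate
    many matrices over the same label set.
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("enumeration needs at least 3 taxa")
    base = (((taxa[0], -1), (taxa[1], -1), (taxa[2], -1)),)
    trees = base
    next_internal = -2
    for k in range(3, n):
        leaf = taxa[k]
        grown = []
        for edges in trees:
            for idx, (u, v) in enumerate(edges):
                mid = next_internal
                new_edges = (
                    edges[:idx]
                    + edges[idx + 1 :]
                    + ((u, mid), (v, mid), (leaf, mid))
                )
                grown.append(new_edges)
        trees = tuple(grown)
        next_internal -= 1
    return trees


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    """Yield every unrooted binary topology over ``taxa`` (lengths unset)."""
    taxa = tuple(taxa)
    for edges in _topology_bank(taxa):
        g = nx.Graph()
        for u, v in edges:
            g.add_edge(u, v, length=None)
        yield Tree(g, taxa)


def exhaustive_me_tree(
    dm: DistanceMatrix, max_taxa: int = MAX_EXHAUSTIVE_TAXA
) -> OlsFit:
    """Minimum-evolution optimum by brute force over all topologies.

    Evaluates every unrooted binary topology (feasible for up to
    ``max_taxa`` = 8 leaves, 10395 topologies) and returns the ME-score
    minimiser; ties are broken by the lexicographically smallest Newick
    string.
    """
    if dm.n > max_taxa:
        raise ValueError(f"exhaustive search limited to {max_taxa} taxa")
    if dm.n < 3:
        raise ValueError("need at least 3 taxa")
    best: OlsFit | None = None
    best_newick = ""
    for topo in enumerate_topologies(dm.taxa):
        fit = ols_branch_lengths(topo, dm)
        nwk = fit.tree.to_newick(clamp_negative=False)
        if (
            best is None
            or fit.me_score < best.me_score - CNI_TOL
            or (abs(fit.me_score - best.me_score) <= CNI_TOL and nwk < best_newick)
        ):
            best = fit
            best_newick = nwk
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# end-to-end family tree + simulation helpers
# ---------------------------------------------------------------------------


@dataclass
class FamilyTreeResult:
    """Family tree with its inputs and search trace."""

    tree: Tree
    newick: str
    distances: DistanceMatrix
    me_score: float
    ssq: float
    trajectory: list[float]


def family_tree(
    aln: Alignment,
    deletion: str = "complete",
    level: int = 1,
) -> FamilyTreeResult:
    """Infer a family tree: Poisson distances -> NJ -> OLS -> CNI.

    Fewer than 2 members raise ``ValueError``; a 2-member family yields
    the trivial single-edge tree.
    """
    if aln.n_taxa < 2:
        raise ValueError("a family tree needs at least 2 members")
    dm = distance_matrix(aln, deletion=deletion)
    start = nj_tree(dm)
    if aln.n_taxa == 2:
        return FamilyTreeResult(
            tree=start,
            newick=start.to_newick(),
            distances=dm,
            me_score=start.me_score,
            ssq=0.0,
            trajectory=[start.me_score],
        )
    result = cni_search(start, dm, level=level)
    return FamilyTreeResult(
        tree=result.tree,
        newick=result.tree.to_newick(),
        distances=dm,
        me_score=result.me_score,
        ssq=result.ssq,
        trajectory=result.trajectory,
    )


def random_tree(
    taxa: Sequence[str],
    rng: np.random.Generator,
    length_range: tuple[float, float] = (0.1, 1.0),
) -> Tree:
    """Random unrooted binary tree with positive branch lengths.

    Topology by random sequential leaf insertion; lengths uniform on
    ``length_range``.  Used to build additive test matrices.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    g = nx.Graph()
    ids = _NodeIds()
    center = ids.new()
    for t in taxa[:3]:
        g.add_edge(t, center)
    for leaf in taxa[3:]:
        edges = sorted(g.edges(), key=lambda e: sorted(map(str, e)))
        u, v = edges[rng.integers(len(edges))]
        mid = ids.new()
        g.remove_edge(u, v)
        g.add_edge(u, mid)
        g.add_edge(v, mid)
        g.add_edge(leaf, mid)
    lo, hi = length_range
    for e in sorted(g.edges(), key=lambda e: sorted(map(str, e))):
        g.edges[e]["length"] = float(rng.uniform(lo, hi))
    return Tree(g, taxa)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Additive (path-length) distance matrix of a fitted tree."""
    n = tree.n_taxa
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = tree.path_length(tree.taxa[i], tree.taxa[j])
    return DistanceMatrix(tree.taxa, d)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(dm.taxa) + "\n")
        for i, t in enumerate(dm.taxa):
            fh.write(t + "\t" + "\t".join(f"{x:.10g}" for x in dm.values[i]) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        vals = []
        for line in fh:
            vals.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    return DistanceMatrix(tuple(header), np.array(vals))
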