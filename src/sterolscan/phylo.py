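"""Distance-based phylogenetics: p-distances, neighbor-joining, outgroup
rooting, and clade-membership queries.

Trees are carried as :mod:`dendropy` objects wrapped in :class:`PhyloTree`.
The neighbor-joining implementation is the classical Saitou–Nei algorithm
(Q-criterion, standard limb-length formulas) with deterministic
lexicographic tie-breaking, so additive distance matrices are recovered
exactly (topology and path lengths). Negative branch lengths are clamped
to zero with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .align import MultipleAlignment

#: cap for the Poisson-corrected distance as p -> 1
MAX_CORRECTED_DISTANCE = 25.0

_TIE_EPS = 1e-12


class IncomparablePairError(ValueError):
    """A taxon pair shares no mutually ungapped alignment column."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if np.any(v < 0) or np.any(np.abs(np.diag(v)) > 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        for tid in self.ids:
            if any(ch in tid for ch in "():;, '\""):
                raise ValueError(f"taxon id {tid!r} contains newick-reserved characters")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("taxon ids must be unique")

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=tuple(df.index), values=df.to_numpy(dtype=float))


def pairwise_distances(msa: MultipleAlignment, method: str = "p_distance") -> DistanceMatrix:
    """Distances over mutually ungapped columns.

    ``p_distance`` is the mismatch fraction; ``poisson_corrected`` is
    ``-ln(1 - p)``, capped at :data:`MAX_CORRECTED_DISTANCE` as p -> 1.
    """
    if method not in ("p_distance", "poisson_corrected"):
        raise ValueError(f"unknown distance method {method!r}")
    if len(msa.ids) < 3:
        raise ValueError("need at least 3 taxa")
    if msa.n_columns < 1:
        raise ValueError("alignment has no columns")
    n = len(msa.ids)
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in msa.rows]
    gap = b"-"
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != gap) & (rows[j] != gap)
            total = int(ok.sum())
            if total == 0:
                raise IncomparablePairError(
                    f"taxa {msa.ids[i]!r} and {msa.ids[j]!r} share no comparable columns"
                )
            p = float((rows[i][ok] != rows[j][ok]).sum()) / total
            if method == "poisson_corrected":
                d = -math.log(1.0 - p) if p < 1.0 else MAX_CORRECTED_DISTANCE
                d = min(d, MAX_CORRECTED_DISTANCE)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=msa.ids, values=mat)


@dataclass
class PhyloTree:
    """A (possibly rooted) tree with branch lengths and unique leaf labels."""

    dtree: dendropy.Tree
    rooted: bool = False

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(dtree=tree, rooted=rooted)

    def newick(self) -> str:
        s = self.dtree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return s.strip()

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self.dtree.leaf_node_iter())

    def leaf_distance(self, a: str, b: str) -> float:
        pdm = self.dtree.phylogenetic_distance_matrix()
        ta = self.dtree.taxon_namespace.get_taxon(a)
        tb = self.dtree.taxon_namespace.get_taxon(b)
        return float(pdm.distance(ta, tb))


def _clamp(length: float, context: str) -> float:
    if length < 0:
        warnings.warn(f"negative branch length {length:.6g} clamped to 0 ({context})")
        return 0.0
    return float(length)


class _Cluster:
    __slots__ = ("label", "children", "key")

    def __init__(self, label=None, children=(), key=None):
        self.label = label
        self.children = list(children)  # (child, branch_length)
        self.key = key if key is not None else label

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.12g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; unrooted (trifurcating central node).

    Pair choice minimizes the Q-criterion; ties are broken by the
    lexicographically smallest (pair of) contained taxon labels.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [_Cluster(label=tid) for tid in dm.ids]
    D = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [
            (i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] <= qmin + _TIE_EPS
        ]
        i, j = min(candidates, key=lambda ij: tuple(sorted((nodes[ij[0]].key, nodes[ij[1]].key))))
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li = _clamp(li, f"join {nodes[i].key}")
        lj = _clamp(lj, f"join {nodes[j].key}")
        parent = _Cluster(
            children=[(nodes[i], li), (nodes[j], lj)],
            key=min(nodes[i].key, nodes[j].key),
        )
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[:-1, -1] = newD[-1, :-1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = newD

    a, b, c = nodes
    la = _clamp(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), f"terminal {a.key}")
    lb = _clamp(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), f"terminal {b.key}")
    lc = _clamp(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), f"terminal {c.key}")
    root = _Cluster(children=[(a, la), (b, lb), (c, lc)], key=min(a.key, b.key, c.key))
    newick = root.newick() + ";"
    return PhyloTree.from_newick(newick, rooted=False)


def _leafset(node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root on the branch separating the outgroup taxa from the ingroup.

    The outgroup must be monophyletic on the unrooted topology; otherwise a
    ``ValueError`` names the intruding taxa. The original branch is split
    in half at the new root, so leaf-to-leaf path lengths are unchanged.
    """
    outgroup = frozenset(outgroup)
    work = tree.dtree.clone(depth=1)
    all_taxa = frozenset(l.taxon.label for l in work.leaf_node_iter())
    missing = outgroup - all_taxa
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    if not outgroup or outgroup == all_taxa:
        raise ValueError("outgroup must be a proper non-empty subset of the taxa")

    target = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        below = _leafset(node)
        if below == outgroup or below == all_taxa - outgroup:
            target = node
            break
    if target is None:
        # name the intruders: taxa inside the smallest clade covering the
        # outgroup that are not outgroup members
        best = None
        for node in work.preorder_node_iter():
            below = _leafset(node)
            if outgroup <= below and (best is None or len(below) < len(best)):
                best = below
        intruders = sorted(best - outgroup) if best else []
        raise ValueError(f"outgroup is not monophyletic; intruding taxa: {intruders}")

    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    work.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    work.is_rooted = True
    return PhyloTree(dtree=work, rooted=True)


def clade_membership(
    tree: PhyloTree, groups: Mapping[str, str]
) -> tuple[dict[str, bool], dict[str, str]]:
    """Per-group monophyly verdicts and nearest-group assignment of
    unlabeled tips.

    A group is monophyletic iff its taxa are exactly the leaves of one
    clade. Each unlabeled tip is assigned the group of its smallest
    enclosing clade that contains labeled taxa, provided those labeled
    taxa all share one group; otherwise ``"unassigned"``.
    """
    if not tree.rooted:
        raise ValueError("clade membership requires a rooted tree")
    labeled = {l for l in tree.leaf_labels if l in groups}
    if not labeled:
        raise ValueError("tree has no labeled taxa")

    leafsets: dict = {}
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset({node.taxon.label})
        else:
            leafsets[node] = frozenset().union(*(leafsets[c] for c in node.child_nodes()))

    monophyly: dict[str, bool] = {}
    for group in sorted(set(groups.values())):
        tips = frozenset(t for t, g in groups.items() if g == group and t in labeled)
        monophyly[group] = any(leafsets[n] == tips for n in leafsets)

    assignments: dict[str, str] = {}
    parent = {c: n for n in tree.dtree.preorder_node_iter() for c in n.child_nodes()}
    for leaf in tree.dtree.leaf_node_iter():
        label = leaf.taxon.label
        if label in groups:
            continue
        node = parent.get(leaf)
        verdict = "unassigned"
        while node is not None:
            under = {groups[t] for t in leafsets[node] if t in groups}
            if under:
                verdict = under.pop() if len(under) == 1 else "unassigned"
                break
            node = parent.get(node)
        assignments[label] = verdict
    return monophyly, assignments
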