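"""Distance-based subfamily classification.

Queries are placed against a labelled reference panel: pairwise
global-alignment identities give a p-distance matrix (distance = 1 -
identity, no substitution-model correction), an in-house neighbor-joining
(NJ) tree is built with deterministic tie-breaking, and each query inherits
the subgroup of its smallest enclosing clade whose reference members vote
unanimously, falling back to the nearest reference when the clade is mixed.
Edge support comes from column-bootstrapping a reference-anchored
pseudo-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align_extract import AlignParams, _align_pair, pairwise_identity
from ._residues import validate_sequence

GAP = "-"


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named taxa."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


class TreeNode:
    """Minimal rooted representation of the (unrooted) NJ tree."""

    __slots__ = ("name", "length", "children", "support")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self, with_support: bool = False) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.2f}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(render(c) for c in self.children)
        return f"({inner});"


@dataclass(frozen=True)
class SubfamilyAssignment:
    """Classification outcome for one query."""

    query_id: str
    family: str
    subgroup: str
    proposed_name: str
    support: float
    method: str  # "nj_clade" | "nearest_ref"


def build_distance_matrix(records: Sequence[tuple[str, str]],
                          params: AlignParams | None = None) -> DistanceMatrix:
    """Pairwise (1 - global-alignment identity) distances."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in records")
    seqs = [validate_sequence(r[1]) for r in records]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = 1.0 - pairwise_identity(seqs[i], seqs[j], params)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=ids, d=d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor-joining agglomeration.

    Ties on the Q-criterion break to the lowest (i, j) pair in current
    matrix order; negative branch lengths are clamped to zero. Returns the
    tree rooted at the final trifurcation (or the 3-taxon star).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    D = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # r[i]+r[j] first keeps Q exactly symmetric in floating point
        Q = (m - 2) * D - (r[:, None] + r[None, :])
        Q[np.tril_indices(m)] = np.inf  # search upper triangle only
        # row-major argmin = lowest (i, j) among tied minima
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        new = TreeNode(children=[child_i, child_j])
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        D = D_new

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, (dab + dac - dbc) / 2)
    b.length = max(0.0, (dab + dbc - dac) / 2)
    c.length = max(0.0, (dac + dbc - dab) / 2)
    return TreeNode(children=[a, b, c])


def tree_distances(root: TreeNode) -> dict[frozenset[str], float]:
    """Path-length metric between all leaf pairs of a tree."""
    dist: dict[frozenset[str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}  # type: ignore[dict-item]
        below: list[dict[str, float]] = []
        for child in node.children:
            sub = walk(child)
            below.append({k: v + child.length for k, v in sub.items()})
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for la, va in below[x].items():
                    for lb, vb in below[y].items():
                        dist[frozenset((la, lb))] = va + vb
        merged: dict[str, float] = {}
        for part in below:
            merged.update(part)
        return merged

    walk(root)
    return dist


def bipartitions(root: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits of the (unrooted) tree, each canonicalised as the
    side that excludes the lexicographically smallest leaf."""
    all_leaves = sorted(root.leaves())
    anchor_leaf = all_leaves[0]
    total = set(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}  # type: ignore[arg-type]
        below: set[str] = set()
        for c in node.children:
            below |= walk(c)
        if 2 <= len(below) <= len(total) - 2:
            side = below if anchor_leaf not in below else total - below
            splits.add(frozenset(side))
        return below

    for c in root.children:
        walk(c)
    return splits


def _path_to_leaf(root: TreeNode, leaf_name: str) -> list[TreeNode] | None:
    if root.is_leaf:
        return [root] if root.name == leaf_name else None
    for child in root.children:
        sub = _path_to_leaf(child, leaf_name)
        if sub is not None:
            return [root] + sub
    return None


def nearest_reference(query_id: str, refs: Mapping[str, str],
                      dm: DistanceMatrix) -> str:
    """Reference id at minimal distance from the query (ties break to the
    lexicographically smallest id)."""
    best = min(sorted(refs), key=lambda r: (dm.get(query_id, r), r))
    return best


def next_free_name(subgroup: str, existing_names: Iterable[str]) -> str:
    """Next unused member number within a subgroup, e.g. 'BvPIP2;5'."""
    import re

    pat = re.compile(rf"^Bv{re.escape(subgroup)};(\d+)$")
    used = [int(m.group(1)) for name in existing_names
            if (m := pat.match(name))]
    return f"Bv{subgroup};{max(used, default=0) + 1}"


def assign_subfamily(query_id: str, tree: TreeNode, refs: Mapping[str, str],
                     dm: DistanceMatrix,
                     existing_names: Iterable[str] = ()) -> SubfamilyAssignment:
    """Assign family/subgroup to a query leaf of a tree built over the
    query and a labelled reference panel (``refs``: id -> subgroup)."""
    if not refs:
        raise ValueError("reference panel must be non-empty")
    path = _path_to_leaf(tree, query_id)
    if path is None:
        raise ValueError(f"query {query_id!r} not in tree")

    subgroup = None
    method = "nearest_ref"
    for ancestor in reversed(path[:-1]):
        clade_refs = {l for l in ancestor.leaves() if l in refs and l != query_id}
        if not clade_refs:
            continue
        labels = {refs[l] for l in clade_refs}
        if len(labels) == 1:
            subgroup = labels.pop()
            method = "nj_clade"
        break  # smallest enclosing clade with references decides

    if subgroup is None:
        subgroup = refs[nearest_reference(query_id, refs, dm)]
        method = "nearest_ref"

    in_subgroup = {r: s for r, s in refs.items() if s == subgroup}
    nearest = nearest_reference(query_id, in_subgroup, dm)
    support = 1.0 - dm.get(query_id, nearest)
    family = "".join(c for c in subgroup if c.isalpha())
    return SubfamilyAssignment(
        query_id=query_id, family=family, subgroup=subgroup,
        proposed_name=next_free_name(subgroup, existing_names),
        support=support, method=method,
    )


def reference_anchored_alignment(records: Sequence[tuple[str, str]],
                                 params: AlignParams | None = None
                                 ) -> tuple[list[str], np.ndarray]:
    """Stack every sequence onto the columns of the first record.

    Each non-reference sequence is aligned pairwise to the reference and its
    residues are projected onto reference columns (query insertions are
    dropped, deletions become gaps). Returns (ids, char matrix of shape
    n_records x len(reference)).
    """
    params = params or AlignParams()
    ids = [r[0] for r in records]
    ref_id, ref_seq = records[0]
    ref_seq = validate_sequence(ref_seq)
    ncol = len(ref_seq)
    rows = [list(ref_seq)]
    for rid, seq in records[1:]:
        seq = validate_sequence(seq)
        aq, ar, _ = _align_pair(seq, ref_seq, params)
        row = []
        for qc, rc in zip(aq, ar):
            if rc != GAP:
                row.append(qc)
        assert len(row) == ncol
        rows.append(row)
    return ids, np.array(rows, dtype="U1")


def _pdistance_matrix(columns: np.ndarray) -> np.ndarray:
    """p-distances between rows of a char matrix, ignoring gapped columns
    pairwise. Pairs with no comparable column get distance 1."""
    n = columns.shape[0]
    d = np.zeros((n, n))
    valid = columns != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                dist = 1.0
            else:
                dist = float((columns[i][both] != columns[j][both]).sum()) / total
            d[i, j] = d[j, i] = dist
    return d


@dataclass
class BootstrapResult:
    tree: TreeNode
    supports: dict[frozenset[str], float]
    replicates: int

    def annotate(self) -> TreeNode:
        """Write supports onto the tree's internal nodes (in place)."""
        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}  # type: ignore[arg-type]
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            for split, frac in self.supports.items():
                if below == set(split) or below == all_set - set(split):
                    node.support = frac
            return below

        all_set = set(self.tree.leaves())
        walk(self.tree)
        return self.tree


def bootstrap_support(records: Sequence[tuple[str, str]], replicates: int,
                      seed: int,
                      params: AlignParams | None = None) -> BootstrapResult:
    """Column-bootstrap edge support for the NJ tree over ``records``.

    Builds a reference-anchored pseudo-alignment, computes the main NJ tree
    from its p-distances, then resamples columns ``replicates`` times and
    records for every split of the main tree the fraction of replicate trees
    containing it. Reproducible for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids, columns = reference_anchored_alignment(records, params)
    main = nj_tree(DistanceMatrix(ids=ids, d=_pdistance_matrix(columns)))
    target_splits = bipartitions(main)
    counts = {split: 0 for split in target_splits}
    rng = np.random.default_rng(seed)
    ncol = columns.shape[1]
    for _ in range(replicates):
        take = rng.integers(0, ncol, size=ncol)
        rep = nj_tree(DistanceMatrix(ids=ids,
                                     d=_pdistance_matrix(columns[:, take])))
        rep_splits = bipartitions(rep)
        for split in target_splits:
            if split in rep_splits:
                counts[split] += 1
    supports = {s: c / replicates for s, c in counts.items()}
    return BootstrapResult(tree=main, supports=supports, replicates=replicates)
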