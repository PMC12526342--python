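"""Cosine genetic distances, neighbor-joining trees, SNP bootstrap support,
and Newick export.

The pairwise distance between two samples is 1 - cos(x, y) over their
dosage vectors restricted to sites called in both. Trees are built with the
Saitou-Nei neighbor-joining agglomeration (deterministic lowest-index
tie-break, negative branch lengths clipped to zero). Node support comes
from resampling SNP columns with replacement, rebuilding distance + tree,
and counting how often each internal-edge leaf bipartition of the
reference tree recurs, as a percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import MISSING, GenotypeMatrix, ValidationError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (len(self.sample_ids),) * 2:
            raise ValidationError("distance matrix shape mismatch")
        if np.isnan(m).any():
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")


@dataclass
class TreeNode:
    """A rooted-representation node of an (unrooted) NJ tree."""

    name: str | None = None
    length: float = 0.0          # branch length to parent
    support: float | None = None  # bootstrap percentage, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode
    clipped_deficit: float = 0.0  # total negative branch length clipped away

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each bipartition is canonicalized as the frozenset of the smaller
        side (lexicographic tie-break), so comparison is orientation-free.
        """
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset] = set()
        def walk(node: TreeNode):
            for child in node.children:
                side = frozenset(lf.name for lf in child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    other = all_leaves - side
                    canon = min(side, other, key=lambda s: (len(s), sorted(s)))
                    out.add(canon)
                walk(child)
        walk(self.root)
        return out

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        D = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            below: list[dict[int, float]] = []
            for child in node.children:
                sub = {k: v + child.length for k, v in walk(child).items()}
                below.append(sub)
            for a in range(len(below)):
                for b in range(a + 1, len(below)):
                    for i, di in below[a].items():
                        for j, dj in below[b].items():
                            D[i, j] = D[j, i] = di + dj
            merged: dict[int, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return names, D


def cosine_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 - cosine similarity of dosage vectors, missing-aware."""
    if gm.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    n = gm.n_samples
    d = gm.dosage.astype(float)
    called = gm.called_mask()
    out = np.zeros((n, n))
    zero_norm = False
    for i in range(n):
        for j in range(i + 1, n):
            ok = called[i] & called[j]
            if not ok.any():
                raise ValidationError(
                    f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} "
                    "share no non-missing site"
                )
            x, y = d[i, ok], d[j, ok]
            nx, ny = np.linalg.norm(x), np.linalg.norm(y)
            if nx == 0 or ny == 0:
                zero_norm = True
                dist = 1.0
            else:
                dist = 1.0 - float(x @ y) / (nx * ny)
            out[i, j] = out[j, i] = max(0.0, dist)
    if zero_norm:
        warnings.warn("zero-norm dosage vector; distance set to 1 for that pair")
    return DistanceMatrix(list(gm.sample_ids), out)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion minimum is taken at the lexicographically lowest index
    pair on ties; the final three nodes are joined at an (unrooted)
    trifurcating root with the three-point branch lengths. Negative branch
    lengths are clipped to zero and the clipped total is recorded.
    """
    dm.validate()
    n = len(dm.sample_ids)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 samples")
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.sample_ids]
    D = dm.matrix.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clip(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # row-major => lowest pair
        ai, aj = sorted(best)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = clip(0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2)))
        lj = clip(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))))
        u = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # grow D with the new node's distances
        newrow = np.array([
            0.5 * (D[i, k] + D[j, k] - dij) for k in range(D.shape[0])
        ])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow
        D[:-1, -1] = newrow
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    i, j, k = active
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = clip(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].length = clip(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].length = clip(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    return PhyloTree(root=root, clipped_deficit=deficit)


def bootstrap_support(gm: GenotypeMatrix, replicates: int = 1000,
                      seed: int = 0) -> PhyloTree:
    """Reference NJ tree with bootstrap support from SNP resampling.

    Each replicate resamples site columns with replacement (same count),
    recomputes cosine distances and the NJ tree, and each internal edge of
    the reference tree is scored by the percentage of replicates whose tree
    contains the same leaf bipartition. ``replicates=0`` returns the
    reference tree with absent support.
    """
    ref = nj_tree(cosine_distance(gm))
    if replicates == 0:
        return ref
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in ref.bipartitions()}
    for _ in range(replicates):
        cols = rng.integers(0, gm.n_sites, size=gm.n_sites)
        # re-key resampled columns so duplicated sites pass validation
        boot = GenotypeMatrix(
            gm.sample_ids,
            gm.sites.iloc[cols].assign(
                position=np.arange(1, gm.n_sites + 1), chromosome="boot"
            ),
            gm.dosage[:, cols],
            sort=False,
        )
        try:
            bps = nj_tree(cosine_distance(boot)).bipartitions()
        except ValidationError:
            continue
        for bp in counts:
            if bp in bps:
                counts[bp] += 1

    all_leaves = frozenset(ref.leaf_names())

    def annotate(node: TreeNode):
        for child in node.children:
            if not child.is_leaf:
                side = frozenset(lf.name for lf in child.leaves())
                canon = min(side, all_leaves - side,
                            key=lambda s: (len(s), sorted(s)))
                if canon in counts:
                    child.support = 100.0 * counts[canon] / replicates
            annotate(child)

    annotate(ref.root)
    return ref


def _newick_label(name: str) -> str:
    if any(ch in name for ch in " \t(),:;'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode, with_lengths: bool = True) -> str:
    if node.is_leaf:
        s = _newick_label(node.name or "")
    else:
        inner = ",".join(_newick_node(c, with_lengths) for c in node.children)
        label = "" if node.support is None else format(node.support, "g")
        s = f"({inner}){label}"
    if with_lengths and node.length is not None:
        s += f":{node.length:g}"
    return s


def to_newick(tree: PhyloTree) -> str:
    inner = ",".join(_newick_node(c) for c in tree.root.children)
    label = "" if tree.root.support is None else format(tree.root.support, "g")
    return f"({inner}){label};"


def write_newick(tree: PhyloTree, path) -> None:
    """Write the tree as Newick with branch lengths and support labels."""
    from pathlib import Path

    Path(path).write_text(to_newick(tree) + "\n")
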