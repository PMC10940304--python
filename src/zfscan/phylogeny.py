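"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

The tree container is :class:`Bio.Phylo.BaseTree.Tree`; neighbor joining is
the Saitou-Nei agglomeration with the standard Q-criterion and limb-length
formulas, returning an unrooted tree (trifurcating root).  Negative limb
lengths are clamped to zero with the deficit moved to the sibling limb so
that path lengths are preserved where possible.

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate, and annotates each internal bipartition of the
full-data tree with the fraction of replicates containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .io_formats import SequenceRecord

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix must be finite")
        np.fill_diagonal(self.d, 0.0)

    def __len__(self) -> int:
        return len(self.labels)


def _msa_array(msa: list[SequenceRecord]) -> tuple[list[str], np.ndarray]:
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(msa[0].residues)
    for rec in msa:
        if len(rec.residues) != length:
            raise ValueError(
                f"aligned sequences must have equal length "
                f"({rec.id!r} has {len(rec.residues)}, expected {length})"
            )
    arr = np.array([list(rec.residues) for rec in msa])
    return [rec.id for rec in msa], arr


def p_distance(msa: list[SequenceRecord]) -> DistanceMatrix:
    """Pairwise-deletion p-distance: mismatches over gap-free columns."""
    labels, arr = _msa_array(msa)
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = np.count_nonzero(arr[i][ok] != arr[j][ok]) / m
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root) tree."""
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Clade] = [Clade(name=lab) for lab in dm.labels]
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = Clade()
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent.clades = [nodes[i], nodes[j]]
        # distances from the new node to every other active node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        active.remove(i)
        active.remove(j)
        active.append(d.shape[0] - 1)
    # resolve the final three nodes around an unrooted central node
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].branch_length = max(length, 0.0)
    root = Clade(clades=[nodes[i], nodes[j], nodes[k]])
    return Tree(root=root, rooted=False)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative limb to 0, moving the deficit to its sibling."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (order: sorted leaf names)."""
    leaves = sorted(tree.get_terminals(), key=lambda c: c.name)
    labels = [c.name for c in leaves]
    n = len(labels)
    d = np.zeros((n, n))
    # accumulate path lengths via root paths
    paths = {c.name: tree.get_path(c) for c in leaves}
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[labels[i]], paths[labels[j]]
            common = 0
            for a, b in zip(pi, pj):
                if a is b:
                    common += 1
                else:
                    break
            dist = sum(c.branch_length or 0.0 for c in pi[common:]) + sum(
                c.branch_length or 0.0 for c in pj[common:]
            )
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, each as the smaller-side
    leaf set's frozenset paired with its complement (canonical: the
    lexicographically smaller frozenset of the two sides)."""
    all_leaves = frozenset(c.name for c in tree.get_terminals())
    splits: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        side = frozenset(c.name for c in clade.get_terminals())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        other = all_leaves - side
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        splits.add(canon)
    return splits


def bootstrap_support(
    msa: list[SequenceRecord], n_replicates: int = 500, seed: int = 0
) -> Tree:
    """NJ tree of the full alignment with bootstrap clade supports in [0, 1].

    Columns are resampled with replacement per replicate (seeded); support
    of each internal bipartition is the fraction of replicate trees that
    contain it, stored as the internal node's ``confidence``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    labels, arr = _msa_array(msa)
    full_tree = nj_tree(p_distance(msa))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = [
            SequenceRecord(id=lab, residues="".join(arr[i, cols]), alphabet="protein")
            for i, lab in enumerate(labels)
        ]
        try:
            rep_splits = bipartitions(nj_tree(p_distance(rep)))
        except ValueError:
            continue  # replicate with an incomparable pair: contributes no splits
        for s in rep_splits:
            counts[s] = counts.get(s, 0) + 1
    all_leaves = frozenset(labels)
    for clade in full_tree.get_nonterminals():
        side = frozenset(c.name for c in clade.get_terminals())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        canon = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
        clade.confidence = counts.get(canon, 0) / n_replicates
    return full_tree
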