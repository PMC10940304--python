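"""Independent reference implementations used to check the package.

Each oracle is deliberately written in a different style from the code it
checks (brute force, exhaustive enumeration, grid search) and never calls
the implementation under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

# --- genetic code (spelled out independently of zfscan.evolution) ---------

_BASES = "ACGT"
_CODE = {}
for _i, (_b1, _b2, _b3) in enumerate(itertools.product("TCAG", repeat=3)):
    _CODE[_b1 + _b2 + _b3] = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[_i]
    )
STOPS = {c for c, a in _CODE.items() if a == "*"}


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Per-codon (S, N): each of the 9 point mutations classified one at a
    time; mutations to stops count as neither."""
    s = n = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOPS:
                continue
            if _CODE[mut] == _CODE[codon]:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


def _paths(a: str, b: str):
    """All orderings of the differing positions, as codon chains."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    for order in itertools.permutations(diffs):
        chain = [a]
        cur = a
        for pos in order:
            cur = cur[:pos] + b[pos] + cur[pos + 1 :]
            chain.append(cur)
        yield chain


def ng86_differences_oracle(a: str, b: str) -> tuple[float, float]:
    """Equal-weight average of (syn, nonsyn) steps over all minimal
    pathways that avoid stop codons (all pathways if none avoids them)."""
    results = []
    fallback = []
    for chain in _paths(a, b):
        sd = nd = 0
        for x, y in zip(chain, chain[1:]):
            if _CODE[x] == _CODE[y]:
                sd += 1
            else:
                nd += 1
        entry = (sd, nd)
        fallback.append(entry)
        if not any(c in STOPS for c in chain[1:-1]):
            results.append(entry)
    use = results or fallback
    return (
        sum(s for s, _ in use) / len(use),
        sum(n for _, n in use) / len(use),
    )


def ng86_oracle(codons_a: list[str], codons_b: list[str]) -> tuple[float, float]:
    """Whole-alignment (ka, ks) by direct summation + JC correction."""
    import math

    S = N = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = ng86_sites_oracle(ca)
        sb, nb = ng86_sites_oracle(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, n = ng86_differences_oracle(ca, cb)
        sd += s
        nd += n
    ps, pn = sd / S, nd / N
    jc = lambda p: float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(pn), jc(ps)


# --- pI grid search -------------------------------------------------------


def pi_grid_oracle(seq: str, charge_fn, step: float = 0.001) -> float:
    """pH grid search: the grid point with the smallest |net charge|."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([charge_fn(seq, ph) for ph in grid])
    return float(grid[np.argmin(np.abs(charges))])


# --- unrooted topology enumeration + least-squares fit --------------------


@lru_cache(maxsize=None)
def unrooted_topologies(n: int) -> tuple:
    """All unrooted binary topologies on leaves 0..n-1, as edge tuples.

    Built by stepwise addition: each new leaf subdivides every existing
    edge.  Internal nodes are numbered from n upward.
    """
    assert n >= 3
    base = (((0, n), (1, n), (2, n)), )  # star on 3 leaves, center n
    topologies = [(list(base[0]), n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_id in topologies:
            for k, (a, b) in enumerate(edges):
                new = edges[:k] + edges[k + 1 :]
                mid = next_id
                nxt.append(
                    (new + [(a, mid), (b, mid), (leaf, mid)], next_id + 1)
                )
        topologies = nxt
    return tuple(tuple(sorted(e)) for e, _ in topologies)


def _leaf_paths(edges: tuple, n: int) -> dict[tuple[int, int], list[int]]:
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    paths = {}
    for i in range(n):
        # DFS from leaf i
        seen = {i: []}
        stack = [i]
        while stack:
            x = stack.pop()
            for y, idx in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + [idx]
                    stack.append(y)
        for j in range(i + 1, n):
            paths[(i, j)] = seen[j]
    return paths


def best_ls_topology(d: np.ndarray) -> tuple[tuple, float]:
    """Brute force over all unrooted topologies: least-squares branch fit,
    return (edges of the best topology, its residual sum of squares)."""
    n = d.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    y = np.array([d[i, j] for i, j in pairs])
    best = None
    for edges in unrooted_topologies(n):
        paths = _leaf_paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        for r, p in enumerate(pairs):
            A[r, paths[p]] = 1.0
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ x - y) ** 2).sum())
        if best is None or rss < best[1]:
            best = (edges, rss)
    return best


def topology_splits(edges: tuple, n: int) -> set[frozenset]:
    """Non-trivial leaf bipartitions induced by the internal edges."""
    adj: dict[int, set[int]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    splits = set()
    for a, b in edges:
        if a < n or b < n:
            continue  # pendant edge
        # leaves on a's side when (a,b) removed
        seen = {a}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((a, b), (b, a)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(l for l in seen if l < n)
        other = frozenset(range(n)) - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def random_additive_matrix(n: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths and its
    exact leaf-to-leaf path-length matrix.  Returns (matrix, splits)."""
    topos = unrooted_topologies(n)
    edges = topos[int(rng.integers(len(topos)))]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    paths = _leaf_paths(edges, n)
    d = np.zeros((n, n))
    for (i, j), idxs in paths.items():
        d[i, j] = d[j, i] = lengths[idxs].sum()
    return d, topology_splits(edges, n)
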