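"""Multilocus linkage disequilibrium and homoplasy tests.

The index of association I_A detects non-random association of alleles
across loci: over all strain pairs, D_ij is the number of loci at which the
pair carries different alleles; I_A = Var(D)/sum_l Var(d_l) - 1, which is 0
under free recombination and approaches (number of loci - 1) for perfectly
clonal data.  Distances are allele-based (0/1 same/different collapsed
allele per locus), the MLST convention.  Significance comes from permuting
allele assignments among strains independently at each locus, normally on
clone-corrected data.

The homoplasy index H measures how much longer the most-parsimonious tree
is than the theoretical minimum, relative to the expectation under free
recombination (site columns shuffled independently across strains):
H = (L_obs - L_min)/(L_free - L_min), clamped to [0, 1].  Parsimony lengths
use Fitch counting on a neighbor-joining tree refined by nearest-neighbor
interchange hill climbing; an exhaustive search over all topologies is
available for small samples as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mlst_io import LocusAlignment, MLSTDataset, collapse_haplotypes

__all__ = [
    "IAResult",
    "HomoplasyResult",
    "locus_alleles",
    "index_of_association",
    "ia_permutation_test",
    "homoplasy_index",
    "parsimony_length",
    "exact_parsimony_length",
]


# ---------------------------------------------------------------------------
# index of association
# ---------------------------------------------------------------------------

def locus_alleles(ds: MLSTDataset, loci=None) -> np.ndarray:
    """(n_strains, n_loci) integer allele ids (collapsed per-locus haplotypes)."""
    names = list(loci) if loci is not None else ds.locus_names
    strains = ds.strains
    cols = []
    for nm in names:
        table = collapse_haplotypes(ds.locus(nm).subset(strains))
        allele_of = {}
        for a_idx, members in enumerate(table.members):
            for sid in members:
                allele_of[sid] = a_idx
        cols.append([allele_of[s] for s in strains])
    return np.asarray(cols, dtype=np.int64).T


def _ia_from_alleles(alleles: np.ndarray) -> float:
    n, n_loci = alleles.shape
    if n < 2:
        raise ValueError("need >= 2 strains")
    iu = np.triu_indices(n, 1)
    # per-locus pair mismatch distances (0/1)
    d = np.stack([(alleles[:, l][:, None] != alleles[:, l][None, :])[iu].astype(float)
                  for l in range(n_loci)])
    D = d.sum(axis=0)
    v_obs = D.var(ddof=1)
    v_exp = sum(d[l].var(ddof=1) for l in range(n_loci))
    if v_exp == 0:
        return 0.0
    return float(v_obs / v_exp - 1.0)


def index_of_association(ds: MLSTDataset, loci=None) -> float:
    """I_A = V_O/V_E - 1 over whole-locus allele mismatch distances."""
    alleles = locus_alleles(ds, loci)
    if alleles.shape[0] < 2:
        raise ValueError("need >= 2 strains")
    if alleles.shape[1] == 1:
        return 0.0
    return _ia_from_alleles(alleles)


@dataclass
class IAResult:
    ia_observed: float
    permutation_values: np.ndarray
    p_value: float
    n_permutations: int
    clone_corrected: bool


def ia_permutation_test(ds: MLSTDataset, loci=None, n_perm: int = 1000,
                        seed: int | None = None,
                        allow_uncorrected: bool = False) -> IAResult:
    """Permutation test of I_A against the free-recombination null.

    The null distribution shuffles allele assignments among strains
    independently at each locus, preserving per-locus allele frequencies
    exactly.  p = (1 + #{perm >= observed})/(1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not ds.clone_corrected and not allow_uncorrected:
        raise ValueError(
            "dataset is not clone-corrected; pass allow_uncorrected=True to override"
        )
    alleles = locus_alleles(ds, loci)
    obs = _ia_from_alleles(alleles) if alleles.shape[1] > 1 else 0.0
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    work = alleles.copy()
    for r in range(n_perm):
        for l in range(work.shape[1]):
            rng.shuffle(work[:, l])
        perms[r] = _ia_from_alleles(work)
    p = (1.0 + np.sum(perms >= obs)) / (1.0 + n_perm)
    return IAResult(obs, perms, float(p), n_perm, ds.clone_corrected)


# ---------------------------------------------------------------------------
# parsimony machinery (Fitch counting on binary trees)
# ---------------------------------------------------------------------------

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}


def _site_matrix(aln: LocusAlignment) -> np.ndarray:
    """(n, n_variable_sites) bitmask-encoded variable columns."""
    arr = aln.masked().to_array()
    variable = np.any(arr != arr[0], axis=0)
    arr = arr[:, variable]
    out = np.zeros(arr.shape, dtype=np.uint8)
    for b, bit in _BITS.items():
        out[arr == b.encode()] = bit
    return out


class _Tree:
    """Rooted binary tree over leaves 0..n-1 (rooting is arbitrary for
    Fitch counting of an unrooted topology)."""

    __slots__ = ("children", "root", "n")

    def __init__(self, children: dict[int, tuple[int, int]], root: int, n: int):
        self.children = children
        self.root = root
        self.n = n

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            if node in self.children:
                stack.extend(self.children[node])
        order.reverse()
        return order

    def copy(self) -> "_Tree":
        return _Tree(dict(self.children), self.root, self.n)


def _fitch_length(tree: _Tree, sites: np.ndarray) -> int:
    """Total Fitch parsimony length over all site columns (vectorized)."""
    states: dict[int, np.ndarray] = {}
    changes = np.zeros(sites.shape[1], dtype=np.int64)
    for node in tree.postorder():
        if node not in tree.children:
            states[node] = sites[node]
        else:
            a, b = tree.children[node]
            inter = states[a] & states[b]
            union = states[a] | states[b]
            empty = inter == 0
            changes += empty
            states[node] = np.where(empty, union, inter)
            del states[a], states[b]
    return int(changes.sum())


def _random_tree(n: int, rng: np.random.Generator) -> _Tree:
    """Random topology by sequential addition in shuffled order."""
    order = rng.permutation(n)
    return _addition_tree(order.tolist(), n)


def _stepwise_tree(order: list[int], sites: np.ndarray) -> _Tree:
    """Greedy stepwise addition: each leaf joins the edge minimizing the
    Fitch length of the grown tree."""
    n = sites.shape[0]
    root = n
    tree = _Tree({root: (order[0], order[1])}, root, n)
    edges = [(root, order[0]), (root, order[1])]
    next_id = n + 1
    for leaf in order[2:]:
        best = None
        for parent, child in edges:
            t = tree.copy()
            new = next_id
            kids = list(t.children[parent])
            kids[kids.index(child)] = new
            t.children[parent] = tuple(kids)
            t.children[new] = (child, leaf)
            length = _fitch_length(t, sites)
            if best is None or length < best[0]:
                cand_edges = [e for e in edges if e != (parent, child)]
                cand_edges += [(parent, new), (new, child), (new, leaf)]
                best = (length, t, cand_edges)
        _, tree, edges = best
        next_id += 1
    return tree


def _addition_tree(order: list[int], n: int) -> _Tree:
    children: dict[int, tuple[int, int]] = {}
    root = n
    next_id = n + 1
    children[root] = (order[0], order[1])
    edges = [(root, order[0]), (root, order[1])]
    for leaf in order[2:]:
        # attach on the first edge (deterministic given order)
        parent, child = edges[0]
        new = next_id
        next_id += 1
        kids = list(children[parent])
        kids[kids.index(child)] = new
        children[parent] = tuple(kids)
        children[new] = (child, leaf)
        edges = edges[1:] + [(parent, new), (new, child), (new, leaf)]
    return _Tree(children, root, n)


def _nj_tree(d: np.ndarray) -> _Tree:
    """Neighbor joining (Saitou & Nei) on a distance matrix; topology only."""
    n = d.shape[0]
    if n == 2:
        return _Tree({2: (0, 1)}, 2, 2)
    active = list(range(n))
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    children: dict[int, tuple[int, int]] = {}
    next_id = 2 * n - 2  # internal ids grow downward is awkward; use counter
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best, pair = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best:
                    best, pair = q, (i, j)
        i, j = pair
        new = next_id
        next_id += 1
        children[new] = (i, j)
        dij = get(i, j)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(new, k), max(new, k))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [a for a in active if a not in (i, j)] + [new]
    # root joins the last three
    a, b, c = active
    inner = next_id
    next_id += 1
    root = next_id
    children[inner] = (a, b)
    children[root] = (inner, c)
    return _Tree(children, root, d.shape[0])


def _nni_neighbors(tree: _Tree):
    """Yield trees one nearest-neighbor interchange away."""
    parent = {}
    for u, (a, b) in tree.children.items():
        parent[a] = u
        parent[b] = u
    for v, (a, b) in tree.children.items():
        if v == tree.root or v not in tree.children:
            continue
        u = parent[v]
        others = [c for c in tree.children[u] if c != v]
        if not others:
            continue
        c = others[0]
        for swap_child in (a, b):
            t = tree.copy()
            keep = b if swap_child is a else a
            t.children[v] = (keep, c)
            kids = list(t.children[u])
            kids[kids.index(c)] = swap_child
            t.children[u] = tuple(kids)
            yield t


def _spr_neighbors(tree: _Tree):
    """Yield trees one subtree-prune-regraft move away (includes all NNIs)."""
    parent = {}
    for u, kids in tree.children.items():
        for k in kids:
            parent[k] = u
    nodes = [v for v in parent if v != tree.root]
    for v in nodes:
        u = parent[v]
        sib = [c for c in tree.children[u] if c != v][0]
        # prune v (and its edge node u)
        pruned = dict(tree.children)
        del pruned[u]
        if u == tree.root:
            if sib not in tree.children:
                continue  # sibling is a leaf; reachable from the other side
            new_root = sib
        else:
            new_root = tree.root
            p = parent[u]
            kids = list(pruned[p])
            kids[kids.index(u)] = sib
            pruned[p] = tuple(kids)
        # leaves/nodes inside the pruned subtree are not regraft targets
        in_subtree = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for c in tree.children.get(x, ()):
                in_subtree.add(c)
                stack.append(c)
        base = _Tree(pruned, new_root, tree.n)
        for x, kids in list(pruned.items()):
            for y in kids:
                if y in in_subtree or (x == u):
                    continue
                t = dict(pruned)
                nk = list(t[x])
                nk[nk.index(y)] = u
                t[x] = tuple(nk)
                t[u] = (y, v)
                yield _Tree(t, new_root, tree.n)


def parsimony_length(sites: np.ndarray, n_restarts: int = 10,
                     seed: int | None = None) -> int:
    """Most-parsimonious tree length by NJ start + NNI hill climbing with
    random-topology restarts; heuristic upper bound on the true length."""
    n = sites.shape[0]
    if n < 2:
        return 0
    if sites.shape[1] == 0:
        return 0
    if n == 2 or n == 3:
        # any topology is equivalent
        tree = _addition_tree(list(range(n)), n) if n == 3 else _Tree({2: (0, 1)}, 2, 2)
        return _fitch_length(tree, sites)
    rng = np.random.default_rng(seed)
    # Hamming distances for NJ start
    d = (sites[:, None, :] != sites[None, :, :]).sum(axis=2).astype(float)
    best_overall = None
    starts = [_nj_tree(d)]
    for _ in range(max(0, n_restarts - 1)):
        order = rng.permutation(n).tolist()
        starts.append(_stepwise_tree(order, sites))
    for tree in starts:
        length = _fitch_length(tree, sites)
        improved = True
        while improved:
            improved = False
            best_cand, best_len = None, length
            for cand in _spr_neighbors(tree):
                l2 = _fitch_length(cand, sites)
                if l2 < best_len:
                    best_cand, best_len = cand, l2
            if best_cand is not None:
                tree, length = best_cand, best_len
                improved = True
        if best_overall is None or length < best_overall:
            best_overall = length
    return int(best_overall)


def exact_parsimony_length(sites: np.ndarray) -> int:
    """Exhaustive search over all unrooted topologies (n <= 8 only)."""
    n = sites.shape[0]
    if n > 8:
        raise ValueError("exhaustive search limited to n <= 8")
    if n <= 3:
        return parsimony_length(sites, n_restarts=1, seed=0)

    best = None

    def build(trees_edges):
        nonlocal best
        tree, edges, nxt, leaf = trees_edges
        if leaf == n:
            length = _fitch_length(tree, sites)
            if best is None or length < best:
                best = length
            return
        for parent, child in list(edges):
            t = tree.copy()
            new = nxt
            kids = list(t.children[parent])
            kids[kids.index(child)] = new
            t.children[parent] = tuple(kids)
            t.children[new] = (child, leaf)
            new_edges = [e for e in edges if e != (parent, child)]
            new_edges += [(parent, new), (new, child), (new, leaf)]
            build((t, new_edges, nxt + 1, leaf + 1))

    root = n
    base = _Tree({root: (0, 1)}, root, n)
    # attach leaf 2 to make the unrooted 3-leaf base
    base.children[n + 1] = (1, 2)
    base.children[root] = (0, n + 1)
    edges = [(root, 0), (root, n + 1), (n + 1, 1), (n + 1, 2)]
    build((base, edges, n + 2, 3))
    return int(best)


# ---------------------------------------------------------------------------
# homoplasy index
# ---------------------------------------------------------------------------

@dataclass
class HomoplasyResult:
    h_index: float | None
    observed_length: int
    min_steps: int
    free_length: float
    n_shuffles: int
    details: dict = field(default_factory=dict)


def homoplasy_index(aln: LocusAlignment, n_shuffles: int = 100,
                    seed: int | None = None, n_restarts: int = 10) -> HomoplasyResult:
    """Homoplasy index H = clamp((L_obs - L_min)/(L_free - L_min), 0, 1).

    L_min is the sum over sites of (observed states - 1); L_free is the mean
    parsimony length after independently permuting each site column across
    strains (free-recombination expectation).  H is None when L_free = L_min
    (no resolvable signal).
    """
    if aln.n < 4:
        raise ValueError("homoplasy test requires >= 4 sequences")
    sites = _site_matrix(aln)
    informative = np.array([
        np.sum(np.unique(col, return_counts=True)[1] >= 2) >= 2
        for col in sites.T
    ])
    if informative.sum() < 2:
        raise ValueError("need >= 2 parsimony-informative sites")
    rng = np.random.default_rng(seed)
    l_min = int(sum(len(np.unique(col)) - 1 for col in sites.T))
    l_obs = parsimony_length(sites, n_restarts=n_restarts,
                             seed=int(rng.integers(2 ** 31)))
    free_lengths = []
    for _ in range(n_shuffles):
        shuffled = sites.copy()
        for c in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, c])
        free_lengths.append(parsimony_length(
            shuffled, n_restarts=max(1, n_restarts // 2),
            seed=int(rng.integers(2 ** 31))))
    l_free = float(np.mean(free_lengths))
    if l_free <= l_min:
        return HomoplasyResult(None, l_obs, l_min, l_free, n_shuffles)
    h = (l_obs - l_min) / (l_free - l_min)
    h = float(min(1.0, max(0.0, h)))
    return HomoplasyResult(h, l_obs, l_min, l_free, n_shuffles,
                           details={"free_lengths": free_lengths})
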