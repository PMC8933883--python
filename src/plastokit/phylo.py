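"""Distance-based tree inference with bootstrap support, and
bipartition-level tree comparison.

The engine is Saitou & Nei neighbor-joining over p/JC69/K2P distances with
column-resampling bootstrap; splits are compared as sets of non-trivial
bipartitions (the basis of the barcode discrimination score and of the
Robinson-Foulds distance).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from ._seq import seq_to_array
from .errors import SaturationError
from .diversity import RegionAlignment


@dataclass
class DistanceMatrix:
    taxa: List[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")


def _pair_distance(a, b, valid_a, valid_b, model, pair):
    ok = valid_a & valid_b
    m = int(ok.sum())
    if m == 0:
        raise SaturationError(f"no shared sites for pair {pair}")
    x, y = a[ok], b[ok]
    diff = x != y
    p = diff.mean()
    if model == "p":
        return p
    if model == "JC69":
        if p >= 0.75:
            raise SaturationError(f"JC69 saturated for pair {pair} (p={p:.3f})")
        return -0.75 * np.log(1 - 4 * p / 3)
    if model == "K2P":
        # transitions: A<->G, C<->T  (codes 0<->2, 1<->3)
        ts = diff & (np.abs(x.astype(int) - y.astype(int)) == 2)
        P = ts.mean()
        Q = p - P
        w1 = 1 - 2 * P - Q
        w2 = 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError(f"K2P saturated for pair {pair}")
        return -0.5 * np.log(w1) - 0.25 * np.log(w2)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(alignment: RegionAlignment, model: str = "JC69"
                    ) -> DistanceMatrix:
    """Pairwise model-corrected distances with pairwise deletion of gap/N
    sites."""
    if len(alignment.taxa) < 3:
        raise ValueError("need >= 3 taxa")
    arr = np.vstack([seq_to_array(r.replace("-", "N")) for r in alignment.rows])
    valid = arr < 4
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(
                arr[i], arr[j], valid[i], valid[j], model,
                (alignment.taxa[i], alignment.taxa[j]))
    return DistanceMatrix(taxa=list(alignment.taxa), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei NJ; Q ties broken by the smallest (i, j) index pair;
    negative branch lengths clamped to 0 with a warning."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    ns = dendropy.TaxonNamespace(dm.taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for t in dm.taxa:
        nd = dendropy.Node(taxon=ns.get_taxon(t))
        nodes.append(nd)
    D = dm.d.copy()
    active = list(range(n))
    clamped = False

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                val = q[ai, aj]
                if best is None or val < best[0] - 1e-12:
                    best = (val, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = li
        parent.add_child(nodes[j]); nodes[j].edge.length = lj
        D = np.pad(D, ((0, 1), (0, 1)))
        new = D.shape[0] - 1
        for a in active:
            if a in (i, j):
                continue
            D[new, a] = D[a, new] = 0.5 * (D[i, a] + D[j, a] - dij)
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [new]

    i, j, k = active
    root = dendropy.Node()
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = ln
    tree.seed_node = root
    tree.is_rooted = False
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return tree


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def tree_splits(tree: dendropy.Tree) -> Set[FrozenSet[str]]:
    """Non-trivial splits as frozensets of tip labels, canonicalised by the
    side NOT containing the lexicographically smallest tip."""
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(labels)
    splits = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels - side)
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side)
    return splits


@dataclass(frozen=True)
class SplitComparison:
    fraction: float
    rf: int
    n_shared_tips: int


def shared_split_fraction(test_tree: dendropy.Tree, ref_tree: dendropy.Tree
                          ) -> SplitComparison:
    """|splits(test) & splits(ref)| / |splits(ref)| over non-trivial splits of
    the shared tip set, plus the RF (symmetric difference) distance."""
    tips_t = {lf.taxon.label for lf in test_tree.leaf_node_iter()}
    tips_r = {lf.taxon.label for lf in ref_tree.leaf_node_iter()}
    shared = tips_t & tips_r
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared tips; need >= 4")
    tt, rt = test_tree, ref_tree
    if shared != tips_t:
        tt = tt.clone(depth=1)
        tt.retain_taxa_with_labels(sorted(shared))
    if shared != tips_r:
        rt = rt.clone(depth=1)
        rt.retain_taxa_with_labels(sorted(shared))
    st, sr = tree_splits(tt), tree_splits(rt)
    frac = len(st & sr) / len(sr) if sr else 1.0
    return SplitComparison(fraction=frac, rf=len(st ^ sr),
                           n_shared_tips=len(shared))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class SupportTree:
    tree: dendropy.Tree
    supports: Dict[FrozenSet[str], float]   # split -> support in [0, 100]
    n_reps: int
    n_skipped: int = 0

    def internal_supports(self) -> List[float]:
        return list(self.supports.values())

    def n_supported(self, threshold: float = 75.0) -> int:
        """Internal edges with support strictly above the threshold."""
        return sum(1 for v in self.supports.values() if v > threshold)


def bootstrap_support(alignment: RegionAlignment, n_reps: int, seed: int,
                      model: str = "JC69") -> SupportTree:
    """NJ tree of the alignment with column-resampling bootstrap supports.

    Replicates whose distance matrix saturates are skipped and counted;
    support is the percentage of completed replicates containing each
    original-tree internal split. Deterministic under ``seed``.
    """
    if len(alignment.taxa) < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    base = neighbor_joining(distance_matrix(alignment, model))
    base_splits = tree_splits(base)
    counts = {s: 0 for s in base_splits}
    L = alignment.length
    skipped = 0
    done = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, r])
        cols = rng.integers(0, L, size=L)
        rows = ["".join(row[c] for c in cols) for row in alignment.rows]
        rep = RegionAlignment(name=f"{alignment.name}|rep{r}", cls=alignment.cls,
                              taxa=list(alignment.taxa), rows=rows)
        try:
            t = neighbor_joining(distance_matrix(rep, model))
        except SaturationError:
            skipped += 1
            continue
        done += 1
        for s in tree_splits(t):
            if s in counts:
                counts[s] += 1
    supports = {s: (100.0 * c / done if done else 0.0)
                for s, c in counts.items()}
    return SupportTree(tree=base, supports=supports, n_reps=n_reps,
                       n_skipped=skipped)


# ---------------------------------------------------------------------------
# Newick round trip
# ---------------------------------------------------------------------------

def read_newick(source) -> dendropy.Tree:
    """Parse newick from a path or a string."""
    s = str(source)
    if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def write_newick(tree: dendropy.Tree, path=None) -> str:
    out = tree.as_string(schema="newick", suppress_rooting=True,
                         preserve_spaces=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out + "\n")
    return out
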