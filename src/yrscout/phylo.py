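"""Distance trees from protein alignments: neighbor-joining with bootstrap.

Distances are p-distance, Poisson-corrected (-ln(1-p)) or gamma-corrected
(shape a: d = a((1-p)^(-1/a) - 1)) over the columns both sequences share.
Tree building is the canonical Saitou-Nei agglomeration; negative branch
lengths are clamped to zero with the excess moved to the sister branch.
Bootstrap support is the percentage of column-resampled replicate trees
containing each bipartition of the full-data tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9,
                           equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")


@dataclass
class _Node:
    name: str | None = None              # leaf label, None for internal
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def leaves(self) -> set[str]:
        if self.name is not None:
            return {self.name}
        out: set[str] = set()
        for child, _bl in self.children:
            out |= child.leaves()
        return out


def canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset | None:
    """Canonical form of a bipartition: the lexicographically smaller side.
    Returns None for trivial splits (fewer than two taxa on a side)."""
    comp = all_taxa - side
    if min(len(side), len(comp)) < 2:
        return None
    return side if tuple(sorted(side)) < tuple(sorted(comp)) else comp


@dataclass
class TreeResult:
    """Unrooted NJ tree (stored rooted at the final trifurcation)."""

    root: _Node
    labels: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, canonicalised independent of taxon order."""
        all_taxa = frozenset(self.labels)
        out: set[frozenset] = set()

        def _walk(node: _Node) -> None:
            for child, _bl in node.children:
                side = canonical_split(frozenset(child.leaves()), all_taxa)
                if side is not None:
                    out.add(side)
                _walk(child)

        _walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        all_taxa = frozenset(self.labels)

        def _fmt(node: _Node, bl: float | None) -> str:
            if node.name is not None:
                body = node.name
            else:
                inner = ",".join(_fmt(c, b) for c, b in node.children)
                label = ""
                if with_support:
                    side = canonical_split(frozenset(node.leaves()), all_taxa)
                    if side in self.support:
                        label = f"{self.support[side]:.0f}"
                body = f"({inner}){label}"
            return body if bl is None else f"{body}:{(bl or 0.0):.6f}"

        return _fmt(self.root, None) + ";"

    def total_length(self) -> float:
        def _sum(node: _Node) -> float:
            return sum(bl + _sum(c) for c, bl in node.children)
        return _sum(self.root)


# ---------------------------------------------------------------------------
# distances


#: saturation clamp: corrected distances are undefined at p -> 1, so p is
#: capped before the log/power transform (keeps bootstrap replicates finite)
_P_CLAMP = 0.99


def protein_distance(aligned: list[tuple[str, str]], model: str = "poisson",
                     gamma_shape: float = 1.0) -> DistanceMatrix:
    """Pairwise distances over shared non-gap columns of aligned proteins."""
    labels = [name for name, _row in aligned]
    rows = [row for _name, row in aligned]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("aligned rows must have equal length")
    n = len(rows)
    arr = np.array([list(r) for r in rows])
    nongap = arr != "-"
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            ns = int(shared.sum())
            if ns == 0:
                mat[i, j] = mat[j, i] = np.nan
                continue
            p = float((arr[i][shared] != arr[j][shared]).sum()) / ns
            if model == "p-distance":
                d = p
            elif model == "poisson":
                d = -np.log(1.0 - min(p, _P_CLAMP))
            elif model == "gamma":
                a = gamma_shape
                d = a * ((1.0 - min(p, _P_CLAMP)) ** (-1.0 / a) - 1.0)
            else:
                raise ValueError(f"unknown model {model!r}")
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeResult:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to 0 and the deficit transferred to
    the sister branch, preserving the pair's summed length.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes: list[_Node] = [_Node(name=lab) for lab in labels]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = divmod(int(np.argmin(q)), m)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        ai, aj = active[i_s], active[j_s]
        dij = d[ai, aj]
        bl_i = 0.5 * dij + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        bl_j = dij - bl_i
        if bl_i < 0:
            bl_j += bl_i
            bl_i = 0.0
        if bl_j < 0:
            bl_i += bl_j
            bl_j = 0.0
        bl_i, bl_j = max(bl_i, 0.0), max(bl_j, 0.0)
        new = _Node(children=[(nodes[ai], bl_i), (nodes[aj], bl_j)])
        # distances from the new node to the remainder
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for other in active:
            if other in (ai, aj):
                continue
            d[k, other] = d[other, k] = 0.5 * (d[ai, other] + d[aj, other] - dij)
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [k]
    if len(active) == 3:
        a, b, c = active
        dab, dac, dbc = d[a, b], d[a, c], d[b, c]
        bl_a = max(0.0, 0.5 * (dab + dac - dbc))
        bl_b = max(0.0, 0.5 * (dab + dbc - dac))
        bl_c = max(0.0, 0.5 * (dac + dbc - dab))
        root = _Node(children=[(nodes[a], bl_a), (nodes[b], bl_b),
                               (nodes[c], bl_c)])
    else:
        a, b = active
        root = _Node(children=[(nodes[a], d[a, b] / 2.0),
                               (nodes[b], d[a, b] / 2.0)])
    _collapse_zero_edges(root)
    return TreeResult(root, labels)


def _collapse_zero_edges(node: _Node, eps: float = 1e-12) -> None:
    """Splice out internal edges of zero length (unsupported resolution —
    identical taxa then sit in a polytomy/star rather than an arbitrary
    binary shape)."""
    new_children: list[tuple[_Node, float]] = []
    for child, bl in node.children:
        _collapse_zero_edges(child, eps)
        if child.name is None and bl <= eps:
            new_children.extend(child.children)
        else:
            new_children.append((child, bl))
    node.children = new_children


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(aligned: list[tuple[str, str]], n_reps: int = 100,
                      seed: int = 0, model: str = "poisson",
                      gamma_shape: float = 1.0) -> TreeResult:
    """NJ tree on the full alignment, internal edges annotated with the
    percentage of column-resampled replicates containing the same split."""
    full = neighbor_joining(protein_distance(aligned, model, gamma_shape))
    target = full.bipartitions()
    if not target or n_reps <= 0:
        return full
    rng = np.random.default_rng(seed)
    ncols = len(aligned[0][1])
    names = [name for name, _ in aligned]
    rows = np.array([list(row) for _name, row in aligned])
    counts = {bp: 0 for bp in target}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        resampled = ["".join(r) for r in rows[:, cols]]
        try:
            rep = neighbor_joining(protein_distance(
                list(zip(names, resampled)), model, gamma_shape))
        except (ValueError, FloatingPointError):
            continue
        found = rep.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    full.support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return full


def random_additive_matrix(n_taxa: int, rng: np.random.Generator,
                           ) -> tuple[DistanceMatrix, TreeResult]:
    """A random binary tree plus its exact path-length distance matrix.

    Used to exercise NJ consistency: on additive input NJ must recover the
    generating topology and branch lengths.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes: list[_Node] = [_Node(name=lab) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]   # j > i: pop j first
        nodes.pop(j)
        nodes.pop(i)
        nodes.append(_Node(children=[(a, float(rng.uniform(0.05, 0.5))),
                                     (b, float(rng.uniform(0.05, 0.5)))]))
    root = _Node(children=[(nd, float(rng.uniform(0.05, 0.5)))
                           for nd in nodes])
    tree = TreeResult(root, labels)
    # path lengths between leaves
    paths: dict[str, dict[str, float]] = {}

    def _collect(node: _Node) -> dict[str, float]:
        if node.name is not None:
            return {node.name: 0.0}
        below: list[dict[str, float]] = []
        for child, bl in node.children:
            sub = _collect(child)
            below.append({leaf: dist + bl for leaf, dist in sub.items()})
        for da, db in itertools.combinations(below, 2):
            for la, xa in da.items():
                for lb, xb in db.items():
                    paths.setdefault(la, {})[lb] = xa + xb
                    paths.setdefault(lb, {})[la] = xa + xb
        merged: dict[str, float] = {}
        for dd in below:
            merged.update(dd)
        return merged

    _collect(root)
    mat = np.zeros((n_taxa, n_taxa))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i != j:
                mat[i, j] = paths[la][lb]
    return DistanceMatrix(labels, mat), tree
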