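"""Distance-based phylogenetics: Poisson-corrected NJ with bootstrap supports.

The workflow mirrors classic distance phylogenetics of protein families:

1. pairwise *p*-distances from an aligned block (complete- or pairwise-
   deletion gap handling),
2. Poisson correction ``d = -ln(1 - p)`` to substitutions per site,
3. neighbor joining (Saitou & Nei Q-criterion) into an unrooted binary tree,
4. bootstrap supports from column-resampled replicates, mapped onto the
   bipartitions of the full-data tree,
5. collapse of internal edges below a support cutoff (default 50%).

Trees are :class:`dendropy.Tree` objects throughout; Newick I/O goes through
dendropy with canonical child ordering for byte-stable round trips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignedBlock",
    "DistanceMatrix",
    "UndefinedDistanceError",
    "SaturationError",
    "InvalidMatrixError",
    "NewickParseError",
    "read_alignment_fasta",
    "p_distance",
    "poisson_distance",
    "distance_matrix",
    "neighbor_joining",
    "patristic_matrix",
    "tree_bipartitions",
    "bootstrap_supports",
    "BootstrapResult",
    "consensus_collapse",
    "majority_rule_consensus",
    "write_newick",
    "read_newick",
]

GAP = "-"


class UndefinedDistanceError(ValueError):
    """No comparable (ungapped) sites remain for a pair of rows."""


class SaturationError(ValueError):
    """p-distance of 1 cannot be Poisson-corrected (infinite distance)."""


class InvalidMatrixError(ValueError):
    """Distance matrix is not symmetric/non-negative/zero-diagonal."""


class NewickParseError(ValueError):
    """Malformed Newick input."""


@dataclass(frozen=True)
class AlignedBlock:
    """Equal-length aligned amino-acid rows with ``-`` as the gap character."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate sequence ids")
        if self.rows:
            ncol = len(self.rows[0])
            if ncol == 0:
                raise ValueError("zero-length alignment")
            for rid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise ValueError(f"row {rid!r} has length {len(row)} != {ncol}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, columns: Sequence[int]) -> "AlignedBlock":
        """Block restricted to ``columns`` (with repetition), in given order."""
        rows = tuple("".join(row[c] for c in columns) for row in self.rows)
        return AlignedBlock(self.ids, rows)


def read_alignment_fasta(path: str | Path) -> AlignedBlock:
    """Read a pre-aligned protein FASTA into an :class:`AlignedBlock`."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return AlignedBlock(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise InvalidMatrixError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.allclose(values, values.T, atol=1e-9):
            raise InvalidMatrixError("matrix is not symmetric")
        if np.any(values < 0):
            raise InvalidMatrixError("matrix has negative entries")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise InvalidMatrixError("matrix diagonal is not zero")


def p_distance(
    row_i: str,
    row_j: str,
    deletion: str = "pairwise",
    keep_columns: Optional[Sequence[int]] = None,
) -> float:
    """Proportion of differing residues among comparable sites.

    ``deletion='pairwise'`` compares all columns ungapped in *both* rows.
    Complete deletion is a block-level notion (drop columns gapped in *any*
    row); callers implement it by passing the pre-filtered column set as
    ``keep_columns``.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    if deletion not in {"pairwise", "complete"}:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    if deletion == "complete" and keep_columns is None:
        raise ValueError(
            "complete deletion requires the block-level ungapped column set"
        )
    cols = range(len(row_i)) if keep_columns is None else keep_columns
    n_comparable = 0
    n_diff = 0
    for c in cols:
        a, b = row_i[c], row_j[c]
        if a == GAP or b == GAP:
            continue
        n_comparable += 1
        if a != b:
            n_diff += 1
    if n_comparable == 0:
        raise UndefinedDistanceError("no comparable sites between rows")
    return n_diff / n_comparable


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance ``d = -ln(1 - p)`` (substitutions/site)."""
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p-distance {p} outside [0, 1)")
    return float(-np.log1p(-p))


def distance_matrix(
    block: AlignedBlock,
    deletion: str = "complete",
    correction: str = "poisson",
) -> DistanceMatrix:
    """All pairwise distances of an aligned block.

    ``correction`` is ``'poisson'`` or ``'p'`` (uncorrected proportion).
    """
    if correction not in {"poisson", "p"}:
        raise ValueError(f"unknown correction {correction!r}")
    arr = np.array([list(row) for row in block.rows])
    gapped = arr == GAP
    if deletion == "complete":
        keep = np.flatnonzero(~gapped.any(axis=0))
        if keep.size == 0:
            raise UndefinedDistanceError(
                "complete deletion leaves no ungapped columns"
            )
    elif deletion == "pairwise":
        keep = None
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")

    n = block.n_rows
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if keep is not None:
                sub = arr[:, keep]
                comparable = np.ones(keep.size, dtype=bool)
                xi, xj = sub[i], sub[j]
            else:
                comparable = ~(gapped[i] | gapped[j])
                xi, xj = arr[i], arr[j]
            m = int(comparable.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {block.ids[i]!r} and "
                    f"{block.ids[j]!r}"
                )
            p = float((xi[comparable] != xj[comparable]).sum()) / m
            d = poisson_distance(p) if correction == "poisson" else p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(block.ids, out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree from a distance matrix.

    Standard Q-criterion agglomeration.  Ties in Q break to the pair whose
    (sorted) cluster keys -- the lexicographically smallest leaf label in
    each cluster -- are smallest, so output is deterministic.  Negative
    branch-length estimates are clamped to zero with the deficit shifted to
    the sibling edge, preserving leaf-to-leaf path lengths.
    """
    labels = dm.labels
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for label in labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
        keys.append(label)

    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        sums = sub.sum(axis=1)
        Q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        best = min(
            (tuple(sorted((keys[idx[a]], keys[idx[b]]))), int(a), int(b))
            for a, b in cand
            if a < b
        )
        a, b = best[1], best[2]
        i, j = idx[a], idx[b]
        dij = sub[a, b]
        li = dij / 2.0 + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        # distances from the new node to the remaining clusters
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (D[i, k] + D[j, k] - dij) / 2.0
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    # final trifurcation: closed-form branch lengths
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    root = dendropy.Node()
    for k, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(length, 0.0)

    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def patristic_matrix(tree: dendropy.Tree, labels: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, consensus
# ---------------------------------------------------------------------------


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _normalize(side: frozenset[str], all_labels: frozenset[str], ref: str) -> frozenset[str]:
    return frozenset(all_labels - side) if ref in side else side


def tree_bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions of an unrooted tree, keyed canonically.

    Each internal edge splits the leaves in two; the side not containing the
    alphabetically first leaf is the canonical key.  Trivial splits (single
    leaf on one side) are omitted.
    """
    all_labels = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(all_labels)
    n = len(all_labels)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if len(side) < 2 or len(side) > n - 2:
            continue
        out[_normalize(side, all_labels, ref)] = node
    return out


@dataclass
class BootstrapResult:
    """Full-data NJ tree plus per-bipartition bootstrap supports."""

    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    n_reps: int
    n_redrawn: int = 0


def bootstrap_supports(
    block: AlignedBlock,
    n_reps: int = 500,
    seed: Optional[int] = None,
    deletion: str = "complete",
    correction: str = "poisson",
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Column-resampling bootstrap supports on the full-data NJ tree.

    Each replicate resamples alignment columns with replacement to the
    original length, recomputes distances and the NJ tree; the support of
    each internal edge of the full-data tree is the fraction of replicates
    containing its bipartition.  Replicates with an undefined or saturated
    distance are redrawn (counted in ``n_redrawn``).
    """
    full_tree = neighbor_joining(distance_matrix(block, deletion, correction))
    target_bips = tree_bipartitions(full_tree)
    counts = {bip: 0 for bip in target_bips}
    rng = np.random.default_rng(seed)
    n_redrawn = 0
    done = 0
    while done < n_reps:
        cols = rng.integers(0, block.n_cols, size=block.n_cols)
        replicate = block.resample_columns(list(cols))
        try:
            rep_dm = distance_matrix(replicate, deletion, correction)
        except (UndefinedDistanceError, SaturationError):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"bootstrap: exceeded {max_redraws} redraws of degenerate "
                    "replicates"
                )
            continue
        rep_bips = tree_bipartitions(neighbor_joining(rep_dm))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
        done += 1
    supports = (
        {bip: counts[bip] / n_reps for bip in counts} if n_reps > 0 else {}
    )
    _annotate_supports(full_tree, supports)
    return BootstrapResult(
        tree=full_tree, supports=supports, n_reps=n_reps, n_redrawn=n_redrawn
    )


def _annotate_supports(
    tree: dendropy.Tree, supports: dict[frozenset[str], float]
) -> None:
    for bip, node in tree_bipartitions(tree).items():
        if bip in supports:
            node.label = f"{supports[bip]:.3f}"


def consensus_collapse(
    tree: dendropy.Tree,
    supports: dict[frozenset[str], float],
    cutoff: float = 0.5,
) -> dendropy.Tree:
    """Copy of ``tree`` with internal edges of support < ``cutoff`` contracted.

    Multifurcations are allowed in the result; the leaf set is unchanged.
    Every internal edge must have a support entry.
    """
    out = tree.clone(depth=1)
    bips = tree_bipartitions(out)
    missing = [bip for bip in bips if bip not in supports]
    if missing:
        raise ValueError(f"supports missing for {len(missing)} internal edge(s)")
    for bip, node in bips.items():
        if supports[bip] < cutoff:
            node.edge.collapse()
        else:
            node.label = f"{supports[bip]:.3f}"
    out.update_bipartitions(suppress_unifurcations=True)
    return out


def majority_rule_consensus(
    block: AlignedBlock,
    n_reps: int = 500,
    seed: Optional[int] = None,
    cutoff: float = 0.5,
    deletion: str = "complete",
    correction: str = "poisson",
) -> dendropy.Tree:
    """True majority-rule consensus of the bootstrap replicate trees.

    Alternative to mapping supports onto the full-data tree: the consensus
    topology is rebuilt from the replicates themselves (dendropy machinery).
    """
    rng = np.random.default_rng(seed)
    trees = dendropy.TreeList()
    done = 0
    while done < n_reps:
        cols = rng.integers(0, block.n_cols, size=block.n_cols)
        replicate = block.resample_columns(list(cols))
        try:
            rep_dm = distance_matrix(replicate, deletion, correction)
        except (UndefinedDistanceError, SaturationError):
            continue
        trees.append(neighbor_joining(rep_dm))
        done += 1
    return trees.consensus(min_freq=cutoff)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _canonical_sort(tree: dendropy.Tree) -> None:
    """Order children by their smallest descendant leaf label, in place."""

    def key(node: dendropy.Node) -> str:
        return min(leaf.taxon.label for leaf in node.leaf_iter())

    for node in tree.postorder_node_iter():
        if not node.is_leaf():
            node.set_child_nodes(sorted(node.child_nodes(), key=key))


def write_newick(tree: dendropy.Tree, path: Optional[str | Path] = None) -> str:
    """Serialise a tree to Newick with canonical child ordering.

    Branch lengths are written to 6 decimals; internal node labels (bootstrap
    supports, when annotated) are preserved.
    """
    _canonical_sort(tree)
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    s = s.strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick from a string or file path."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        data = Path(source).read_text()
    else:
        data = str(source)
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree
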