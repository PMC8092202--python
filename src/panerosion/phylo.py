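"""Core-gene selection, concatenation, trees and ordination.

Core genes are pseudogene-free orthologous groups with exactly one member
in every genome; their protein alignments are concatenated into a
supermatrix with a 1-based inclusive partition table. Trees are handled as
dendropy objects (Newick-interchangeable); when no externally inferred
tree is available, a neighbor-joining tree on p-distances of the
concatenated alignment serves as a self-contained fallback.

Ordination is classical principal-coordinate analysis (Gower
double-centering of the squared distance matrix followed by
eigendecomposition); tree concordance is quantified by the
Robinson–Foulds distance on the shared leaf set, with a tanglegram
pairing table for display.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .orthology import OrthoGroup

PCOA_METRICS = ("euclidean_binary", "jaccard")


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    text = str(source)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    return dendropy.Tree.get(data=text, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# core genes


def select_core_groups(
    groups: list[OrthoGroup], pseudo_status: dict[str, bool], genome_ids: list[str]
) -> list[OrthoGroup]:
    """Single-copy universal pseudogene-free groups, ordered by group id.

    A core group has exactly one member in each of ``genome_ids`` and no
    member classified as a pseudogene.
    """
    wanted = set(genome_ids)
    core = []
    for group in groups:
        counts: dict[str, int] = {}
        for m in group.members:
            counts[m.genome_id] = counts.get(m.genome_id, 0) + 1
        if set(counts) != wanted or any(v != 1 for v in counts.values()):
            continue
        if any(pseudo_status.get(m.gene_id, False) for m in group.members):
            continue
        core.append(group)
    return sorted(core, key=lambda g: g.group_id)


def concatenate(
    alignments: dict[str, dict[str, str]]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate per-group alignments (genome-keyed rows) in group-id order.

    Returns the supermatrix rows and a partition table with 1-based
    inclusive column intervals per group. Every alignment must cover the
    same genome set.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    group_ids = sorted(alignments)
    genomes = sorted(alignments[group_ids[0]])
    parts = {g: [] for g in genomes}
    rows = []
    start = 1
    for gid in group_ids:
        aln = alignments[gid]
        if sorted(aln) != genomes:
            raise ValueError(f"alignment {gid} does not cover all genomes")
        length = len(next(iter(aln.values())))
        for g in genomes:
            parts[g].append(aln[g])
        rows.append((gid, start, start + length - 1))
        start += length
    supermatrix = {g: "".join(parts[g]) for g in genomes}
    partitions = pd.DataFrame(rows, columns=["group_id", "start", "end"])
    return supermatrix, partitions


def p_distance_matrix(rows: dict[str, str]) -> pd.DataFrame:
    """Pairwise p-distances (mismatch fraction over shared non-gap columns)."""
    ids = sorted(rows)
    arrs = {g: np.frombuffer(rows[g].encode(), dtype=np.uint8) for g in ids}
    gap = ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            ok = (a != gap) & (b != gap)
            total = int(ok.sum())
            d[i, j] = d[j, i] = float((a[ok] != b[ok]).mean()) if total else 0.0
    return pd.DataFrame(d, index=ids, columns=ids)


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree (standard Q-criterion, negative lengths clamped)."""
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    ids = list(distances.index)
    dm = DistanceMatrix(distances.to_numpy(dtype=float), ids)
    sk_tree = _skbio_nj(dm)
    newick = io.StringIO()
    sk_tree.write(newick, format="newick")
    tree = dendropy.Tree.get(data=newick.getvalue(), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# ordination


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # genome x axis
    explained_variance_pct: np.ndarray  # over positive eigenvalues
    eigenvalues: np.ndarray  # all eigenvalues, descending


def binary_distance(matrix: pd.DataFrame, metric: str = "euclidean_binary") -> pd.DataFrame:
    """Distance between genome columns of a 0/1 presence/absence matrix."""
    if metric not in PCOA_METRICS:
        raise ValueError(f"metric must be one of {PCOA_METRICS}")
    genomes = list(matrix.columns)
    x = matrix.to_numpy(dtype=float).T  # genomes x groups
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i], x[j]
            if metric == "euclidean_binary":
                val = np.sqrt(np.sum((a - b) ** 2))
            else:  # jaccard
                union = np.sum((a + b) > 0)
                inter = np.sum((a * b) > 0)
                val = 1.0 - inter / union if union else 0.0
            d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=genomes, columns=genomes)


def pcoa_from_distances(distances: pd.DataFrame) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for positive eigenvalues, axes ordered by
    descending eigenvalue, and each axis is oriented so its first nonzero
    loading is positive. Explained variance percentages are computed over
    the positive eigenvalues only (negative eigenvalues, possible for
    non-Euclidean input, are reported but excluded).
    """
    ids = list(distances.index)
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    positive = eigvals > tol
    if not positive.any():
        coords = pd.DataFrame(np.zeros((n, 0)), index=ids)
        return PcoaResult(coords, np.array([]), eigvals)
    vals = eigvals[positive]
    vecs = eigvecs[:, positive] * np.sqrt(vals)
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if nz.size and col[nz[0]] < 0:
            vecs[:, k] = -col
    pct = 100.0 * vals / vals.sum()
    coords = pd.DataFrame(vecs, index=ids, columns=[f"PCo{k + 1}" for k in range(vecs.shape[1])])
    return PcoaResult(coords, pct, eigvals)


def pcoa(matrix: pd.DataFrame, metric: str = "euclidean_binary") -> PcoaResult:
    """PCoA of genomes from a binary group x genome presence/absence matrix."""
    if matrix.shape[1] < 3:
        raise ValueError("PCoA needs >= 3 genomes")
    return pcoa_from_distances(binary_distance(matrix, metric))


# ---------------------------------------------------------------------------
# tree comparison


def _restricted_bipartitions(tree: dendropy.Tree, shared: set[str]) -> set[frozenset]:
    """Nontrivial bipartitions of the subtree induced on ``shared`` leaves.

    Each bipartition is canonically represented by the side not containing
    the alphabetically first shared leaf.
    """
    anchor = min(shared)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()} & shared
        if len(below) < 2 or len(shared) - len(below) < 2:
            continue
        side = below if anchor not in below else frozenset(shared - below)
        bips.add(frozenset(side))
    return bips


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson–Foulds distance on the shared leaf set.

    Counts bipartitions present in exactly one of the two induced
    subtrees; 0 iff the topologies agree on the shared leaves.
    """
    leaves_a = set(leaf_labels(tree_a))
    leaves_b = set(leaf_labels(tree_b))
    shared = leaves_a & leaves_b
    if len(shared) < 4:
        raise ValueError("trees share fewer than 4 leaves")
    bips_a = _restricted_bipartitions(tree_a, shared)
    bips_b = _restricted_bipartitions(tree_b, shared)
    return len(bips_a ^ bips_b)


@dataclass
class TanglegramPairing:
    pairs: pd.DataFrame  # label, position_a, position_b (ladderized leaf orders)
    unmatched_a: list[str]
    unmatched_b: list[str]


def tanglegram_pairs(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> TanglegramPairing:
    """Leaf pairing between two ladderized trees.

    Shared leaves get their positions in each tree's ladderized leaf
    order; leaves present in only one tree are listed as unmatched (in the
    display these are the strains without connecting lines).
    """
    order_a = _ladderized_order(tree_a)
    order_b = _ladderized_order(tree_b)
    pos_a = {label: i for i, label in enumerate(order_a)}
    pos_b = {label: i for i, label in enumerate(order_b)}
    shared = [label for label in order_a if label in pos_b]
    pairs = pd.DataFrame(
        {
            "label": shared,
            "position_a": [pos_a[s] for s in shared],
            "position_b": [pos_b[s] for s in shared],
        }
    )
    unmatched_a = [s for s in order_a if s not in pos_b]
    unmatched_b = [s for s in order_b if s not in pos_a]
    return TanglegramPairing(pairs=pairs, unmatched_a=unmatched_a, unmatched_b=unmatched_b)


def _ladderized_order(tree: dendropy.Tree) -> list[str]:
    clone = tree.clone(depth=1)
    clone.ladderize()
    return [leaf.taxon.label for leaf in clone.leaf_node_iter()]


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    clone.reroot_at_midpoint(update_bipartitions=False)
    return clone


def root_on_outgroup_and_prune(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the outgroup leaf, then remove it (display convention)."""
    clone = tree.clone(depth=1)
    node = clone.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not found")
    clone.to_outgroup_position(node, update_bipartitions=False)
    clone.prune_taxa_with_labels([outgroup])
    return clone
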