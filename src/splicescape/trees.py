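"""UPGMA feature trees and nodal-distance discordance testing.

Feature divergence matrices are agglomerated by UPGMA (average linkage,
ultrametric heights).  Discordance between a feature tree and reference
trees is quantified by the RMSD between their nodal matrices — the
per-leaf-pair counts of intervening internal nodes — and assessed against
a null obtained by randomly permuting the feature tree's leaf labels on a
fixed topology.  Both a normal-tail p-value (mean/sd of the permutation
null) and an exact permutation rank p-value are reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .divergence import FeatureDistanceMatrix


# ---------------------------------------------------------------------------
# UPGMA


def upgma(matrix: FeatureDistanceMatrix | tuple[list[str], np.ndarray],
          clip_negative: bool = True) -> dendropy.Tree:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Ties in the minimal pair are broken toward the lexicographically
    smallest (label, label) pair, making the construction deterministic.
    Negative divergences are clipped to zero (with a warning from the
    matrix object) before agglomeration.
    """
    if isinstance(matrix, FeatureDistanceMatrix):
        labels = list(matrix.labels)
        D = matrix.clipped() if clip_negative else matrix.values.copy()
    else:
        labels, D = list(matrix[0]), np.array(matrix[1], dtype=float)
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")

    # cluster state: id -> (newick, height, size, min_label)
    clusters: dict[int, tuple[str, float, int, str]] = {
        i: (_quote(labels[i]), 0.0, 1, labels[i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(clusters) > 1:
        # minimal pair; ties -> smallest (min_label_i, min_label_j) sorted pair
        def key(pair: tuple[int, int]) -> tuple[float, tuple[str, str]]:
            i, j = pair
            la, lb = sorted((clusters[i][3], clusters[j][3]))
            return (dist[pair], (la, lb))

        (i, j) = min(dist, key=key)
        d = dist[(i, j)]
        height = d / 2.0
        nwk_i, h_i, size_i, lab_i = clusters[i]
        nwk_j, h_j, size_j, lab_j = clusters[j]
        merged = (f"({nwk_i}:{max(height - h_i, 0.0):.10g},"
                  f"{nwk_j}:{max(height - h_j, 0.0):.10g})")
        new_label = min(lab_i, lab_j)
        # arithmetic-mean distance to every remaining cluster
        new_dists = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dists[k] = (size_i * dik + size_j * djk) / (size_i + size_j)
        del clusters[i], clusters[j]
        dist = {pair: v for pair, v in dist.items()
                if i not in pair and j not in pair}
        for k, v in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = (merged, height, size_i + size_j, new_label)
        next_id += 1

    (newick, _, _, _) = next(iter(clusters.values()))
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    tree.is_rooted = True
    return tree


def _quote(label: str) -> str:
    return label.replace(" ", "_")


# ---------------------------------------------------------------------------
# nodal matrices and RMSD


def nodal_matrix(tree: dendropy.Tree,
                 leaf_order: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Per-leaf-pair counts of internal nodes on the connecting path.

    A cherry pair has 1 intervening node; a multifurcation counts as a
    single internal node.  Returns (sorted leaf labels, symmetric matrix
    with zero diagonal).
    """
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if len(leaves) < 2:
        raise ValueError("nodal matrix needs at least 2 leaves")
    labels = sorted(leaves) if leaf_order is None else list(leaf_order)

    # depth (edge count from root) per node
    depth: dict[int, int] = {}
    parent: dict[int, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + 1
        parent[id(node)] = node.parent_node

    def ancestors(node: dendropy.Node) -> list[dendropy.Node]:
        out = []
        cur = node
        while cur is not None:
            out.append(cur)
            cur = parent[id(cur)]
        return out

    anc = {lab: ancestors(leaves[lab]) for lab in labels}
    anc_sets = {lab: {id(x) for x in anc[lab]} for lab in labels}

    n = len(labels)
    M = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        la, lb = labels[a], labels[b]
        # MRCA: first ancestor of a that is an ancestor of b
        mrca_depth = None
        for node in anc[la]:
            if id(node) in anc_sets[lb]:
                mrca_depth = depth[id(node)]
                break
        assert mrca_depth is not None
        steps = (depth[id(leaves[la])] - mrca_depth) + \
                (depth[id(leaves[lb])] - mrca_depth)
        M[a, b] = M[b, a] = steps - 1  # internal nodes on the path
    return labels, M


def nodal_rmsd(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> float:
    """RMSD over unordered shared-leaf pairs of the two nodal matrices."""
    labels_a, _ = nodal_matrix(tree_a)
    labels_b, _ = nodal_matrix(tree_b)
    shared = sorted(set(labels_a) & set(labels_b))
    if len(shared) < 3:
        raise ValueError("trees share fewer than 3 leaves")
    _, Ma = nodal_matrix(_prune_to(tree_a, shared), leaf_order=shared)
    _, Mb = nodal_matrix(_prune_to(tree_b, shared), leaf_order=shared)
    iu = np.triu_indices(len(shared), k=1)
    return float(np.sqrt(np.mean((Ma[iu] - Mb[iu]) ** 2)))


def _prune_to(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if present == set(labels):
        return tree
    clone = tree.clone(depth=1)
    clone.retain_taxa_with_labels(labels)
    return clone


# ---------------------------------------------------------------------------
# discordance test


@dataclass
class DiscordanceReport:
    """Observed mean RMSD against reference trees plus its permutation null."""

    rmsd: float
    null_mean: float
    null_sd: float
    p_value: float          # lower-tail normal probability
    p_permutation: float    # exact rank among permutations
    n_permutations: int


def _permute_labels(tree: dendropy.Tree, rng: np.random.Generator) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    leaves = list(clone.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    perm = rng.permutation(len(labels))
    for lf, k in zip(leaves, perm):
        lf.taxon = dendropy.Taxon(label=labels[k])
    return clone


def tree_discordance(feature_tree: dendropy.Tree,
                     reference_trees: list[dendropy.Tree],
                     n_perm: int = 100,
                     seed: int = 0) -> DiscordanceReport:
    """Mean nodal RMSD against references, with a label-permutation null.

    The null keeps the feature tree's topology and permutes its leaf
    labels; assuming the null RMSDs are normal, the reported p-value is
    the lower tail probability of the observed statistic.  An exact
    permutation rank p-value accompanies it, since a tail probability far
    below 1/n_perm cannot be supported empirically.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    observed = float(np.mean([nodal_rmsd(feature_tree, ref)
                              for ref in reference_trees]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        permuted = _permute_labels(feature_tree, rng)
        null[t] = np.mean([nodal_rmsd(permuted, ref)
                           for ref in reference_trees])
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd > 0:
        p = float(stats.norm.cdf(observed, loc=mean, scale=sd))
    else:
        p = 1.0 if observed >= mean else 0.0
    p = min(max(p, np.nextafter(0, 1)), 1.0 - 1e-16)
    p_perm = (1 + int((null <= observed).sum())) / (n_perm + 1)
    return DiscordanceReport(rmsd=observed, null_mean=mean, null_sd=sd,
                             p_value=p, p_permutation=p_perm,
                             n_permutations=n_perm)


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick")


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick")
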