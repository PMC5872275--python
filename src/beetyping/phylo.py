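"""Kimura 2-parameter distances, neighbor joining, bootstrap support.

Distance model
--------------
For an aligned pair of sequences let P be the proportion of sites with a
transition (A<->G, C<->T) and Q the proportion with a transversion among the
n sites retained after deletion of gap/ambiguous columns.  The K2P distance is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Pairs for which either logarithm argument is non-positive are *saturated*:
the distance is undefined and a :class:`SaturationError` is raised rather
than substituting an arbitrary large value.

Trees are neighbor-joining (Saitou & Nei agglomeration on the rate-corrected
Q criterion), with lexicographically smallest label pair as the deterministic
tie-break and negative branch-length estimates clamped to zero.  Bootstrap
supports are percentages of column-resampled replicates containing each
internal bipartition of the tree built from the original alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seqcore import CONCRETE_BASES, DnaRecord

__all__ = [
    "SaturationError",
    "K2PResult",
    "DistanceMatrix",
    "k2p_distance",
    "k2p_matrix",
    "GroupDistanceReport",
    "mean_group_distance",
    "nj_tree",
    "bootstrap_support",
    "write_newick",
    "read_newick",
    "tree_bipartitions",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class SaturationError(ValueError):
    """Distance undefined: substitution proportions exceed the model's range."""


@dataclass
class K2PResult:
    d: float
    P: float
    Q: float
    n_sites: int


def _pair_counts(s1: str, s2: str) -> tuple[int, int, int]:
    """(n_usable_sites, transitions, transversions) under pairwise deletion."""
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in CONCRETE_BASES or b not in CONCRETE_BASES:
            continue
        n += 1
        if a != b:
            if frozenset((a, b)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def k2p_distance(seq1: str, seq2: str, deletion: str = "pairwise") -> K2PResult:
    """Kimura 2-parameter distance between two aligned sequences.

    ``deletion`` is accepted for interface symmetry with
    :func:`k2p_matrix`; for a single pair both policies exclude the same
    gap/ambiguous sites.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n, ts, tv = _pair_counts(seq1.upper(), seq2.upper())
    if n == 0:
        raise ValueError("no usable sites after deletion of gaps/ambiguity")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution saturation (P={P:.3f}, Q={Q:.3f}); distance undefined"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d, P, Q, n)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def _mask_complete(seqs: list[str]) -> list[str]:
    keep = [
        i
        for i in range(len(seqs[0]))
        if all(s[i] in CONCRETE_BASES for s in seqs)
    ]
    return ["".join(s[i] for i in keep) for s in seqs]


def k2p_matrix(records: list[DnaRecord], deletion: str = "pairwise") -> DistanceMatrix:
    """Pairwise K2P distance matrix for an alignment.

    ``complete`` deletion removes every column containing a gap or ambiguity
    in any record before computing distances; ``pairwise`` (default, matching
    common barcoding practice) excludes sites per pair.
    """
    seqs = [r.seq for r in records]
    if deletion == "complete":
        seqs = _mask_complete(seqs)
    labels = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(seqs[i], seqs[j], "pairwise").d
    return DistanceMatrix(labels, d)


@dataclass
class GroupDistanceReport:
    within: dict[str, float]  # group -> mean pairwise d (NaN for singletons)
    overall: float
    n_saturated: int = 0


def mean_group_distance(
    records: list[DnaRecord], groups: dict[str, str]
) -> GroupDistanceReport:
    """Mean pairwise K2P distance within groups and overall.

    Saturated pairs are excluded from the averages, counted and warned about.
    Groups with fewer than two members report NaN.
    """
    import warnings

    if len(records) < 2:
        raise ValueError("need at least two records")
    n_sat = 0
    all_d: list[float] = []
    per_group: dict[str, list[float]] = {}
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            try:
                dij = k2p_distance(records[i].seq, records[j].seq).d
            except SaturationError:
                n_sat += 1
                continue
            all_d.append(dij)
            gi, gj = groups.get(records[i].id), groups.get(records[j].id)
            if gi is not None and gi == gj:
                per_group.setdefault(gi, []).append(dij)
    if n_sat:
        warnings.warn(f"{n_sat} saturated pair(s) excluded from mean distances")
    within = {}
    for g in sorted(set(groups.values())):
        members = [r for r in records if groups.get(r.id) == g]
        if len(members) < 2:
            within[g] = float("nan")
        else:
            within[g] = float(np.mean(per_group.get(g, [float("nan")])))
    overall = float(np.mean(all_d)) if all_d else float("nan")
    return GroupDistanceReport(within, overall, n_sat)


def _nj_branch_clamp(v: float) -> float:
    return max(v, 0.0)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest pair of (sorted) node labels, where an
    internal node is labelled by its smallest descendant leaf.  Negative
    branch-length estimates are clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[str, dendropy.Node] = {}
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[lab] = node
    # active set: representative label -> (sort key, node)
    active = {lab: lab for lab in dm.labels}  # label -> min descendant leaf
    d = {
        frozenset((a, b)): float(dm.value(a, b))
        for i, a in enumerate(dm.labels)
        for b in dm.labels[i + 1:]
    }

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[frozenset((a, b))]

    labels = list(dm.labels)
    while len(labels) > 2:
        m = len(labels)
        totals = {a: sum(dist(a, b) for b in labels) for a in labels}
        best = None
        best_pair = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                q = (m - 2) * dist(a, b) - totals[a] - totals[b]
                key = tuple(sorted((active[a], active[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key)
                    best_pair = (a, b)
        a, b = best_pair
        dab = dist(a, b)
        va = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (m - 2))
        vb = dab - va
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length = _nj_branch_clamp(va)
        nb.edge.length = _nj_branch_clamp(vb)
        parent.add_child(na)
        parent.add_child(nb)
        new_label = f"__join_{a}_{b}"
        nodes[new_label] = parent
        active[new_label] = min(active[a], active[b])
        for c in labels:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        labels = [c for c in labels if c not in (a, b)] + [new_label]

    a, b = sorted(labels, key=lambda x: active[x])
    na, nb = nodes[a], nodes[b]
    final = dist(a, b)
    # attach the remaining node as a child of the other to obtain an unrooted
    # (basal trichotomy after suppression) representation
    if nb.is_leaf() and not na.is_leaf():
        na, nb = nb, na
    if nb.is_leaf():
        root = dendropy.Node()
        root.add_child(na)
        root.add_child(nb)
        na.edge.length = na.edge.length or 0.0
        nb.edge.length = _nj_branch_clamp(final)
        tree.seed_node = root
    else:
        na.edge.length = _nj_branch_clamp(final)
        nb.add_child(na)
        tree.seed_node = nb
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side not containing the
    alphabetically first leaf is the canonical representation.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = below if anchor not in below else leaves - below
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset(side))
    return splits


def nj_tree_from_alignment(
    records: list[DnaRecord], deletion: str = "pairwise"
) -> dendropy.Tree:
    return nj_tree(k2p_matrix(records, deletion))


def bootstrap_support(
    records: list[DnaRecord],
    n_reps: int = 500,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal bipartition of the original-alignment tree is
    the percentage of replicate trees containing it (integer, 0-100).
    Replicates whose distance matrix contains a saturated pair are skipped
    and counted in the tree annotation ``n_skipped``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(records) < 3:
        raise ValueError("bootstrap requires >= 3 sequences")
    rng = np.random.default_rng(seed)
    ncol = len(records[0].seq)
    base_tree = nj_tree_from_alignment(records, deletion)
    target = tree_bipartitions(base_tree)
    counts = {s: 0 for s in target}
    n_ok = 0
    n_skipped = 0
    order = sorted(range(len(records)), key=lambda i: records[i].id)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        # taxon-order invariance: resample rows in a label-sorted order
        reps = [
            DnaRecord(records[i].id, "".join(records[i].seq[c] for c in cols))
            for i in order
        ]
        try:
            t = nj_tree_from_alignment(reps, deletion)
        except (SaturationError, ValueError):
            n_skipped += 1
            continue
        n_ok += 1
        found = tree_bipartitions(t)
        for s in target & found:
            counts[s] += 1
    for node in base_tree.preorder_node_iter():
        if node is base_tree.seed_node or node.is_leaf():
            continue
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        all_leaves = {lf.taxon.label for lf in base_tree.leaf_node_iter()}
        anchor = min(all_leaves)
        side = leaves if anchor not in leaves else all_leaves - leaves
        key = frozenset(side)
        if key in counts and n_ok:
            node.label = str(round(100.0 * counts[key] / n_ok))
    base_tree.annotations.add_new("n_skipped", n_skipped)
    return base_tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
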