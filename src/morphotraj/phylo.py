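"""Phylogenetic signal by squared-change parsimony and tip permutation.

A rooted tree with branch lengths carries per-tip trait vectors (here,
size-corrected PC scores of adult group mean shapes).  Internal-node values
are chosen to minimise the total squared change summed over branches,
optionally weighting each branch's squared change by the inverse branch
length; the minimised total ("tree length") measures how well the tip data
fit the tree.  The permutation test compares the observed tree length with
lengths obtained by randomly reassigning the tip vectors to tips: a small
p-value means similarity in trait values tracks relatedness.

With few tips the permutation null is enumerated exhaustively (4 tips give
only 24 assignments), making the test exact and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _permutations

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "read_newick",
    "bear_tree",
    "squared_change_length",
    "phylo_signal_permutation",
    "SignalTestResult",
]

_ENUMERATION_LIMIT = 8  # tips; 8! = 40320 permutations


@dataclass
class PhyloTree:
    """Rooted tree: node ids 0..n-1, parent links and branch lengths.

    ``parent[i]`` is the parent node id of node ``i`` (-1 for the root);
    ``branch_lengths[i]`` is the length of the branch above node ``i``
    (NaN when the file gave none).  Tips are the leaf nodes, in the order
    encountered; ``tip_labels`` names them.
    """

    parent: np.ndarray          # (n_nodes,), int
    branch_lengths: np.ndarray  # (n_nodes,), float, NaN if absent
    tip_ids: np.ndarray         # (n_tips,), int
    tip_labels: tuple[str, ...]
    newick: str = ""

    def __post_init__(self) -> None:
        if self.tip_ids.size < 2:
            raise ValueError("a tree needs at least 2 tips")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        lengths = self.branch_lengths[1:]  # root branch ignored
        if np.any(lengths[~np.isnan(lengths)] < 0):
            raise ValueError("branch lengths must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    nodes = list(tree.preorder_node_iter())
    index = {id(node): i for i, node in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.full(len(nodes), np.nan)
    tip_ids: list[int] = []
    tip_labels: list[str] = []
    for i, node in enumerate(nodes):
        if node.parent_node is not None:
            parent[i] = index[id(node.parent_node)]
        if node.edge.length is not None:
            lengths[i] = float(node.edge.length)
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else None
            if not label:
                raise ValueError("every tip must carry a label")
            tip_ids.append(i)
            tip_labels.append(label)
    return PhyloTree(
        parent=parent,
        branch_lengths=lengths,
        tip_ids=np.asarray(tip_ids, dtype=int),
        tip_labels=tuple(tip_labels),
        newick=text.strip(),
    )


def bear_tree(branch_mode: str = "unit_lengths",
              divergence_times: dict | None = None) -> PhyloTree:
    """The four-species study topology (americanus, (spelaeus, (arctos, maritimus))).

    ``unit_lengths`` sets every branch to 1.  With ``given_lengths`` the
    caller supplies divergence times (Ma) for the three internal splits as
    ``{"root": t0, "spelaeus_split": t1, "arctos_maritimus": t2}`` and
    branch lengths are derived from the ultrametric depths.
    """
    if branch_mode == "unit_lengths":
        newick = "(americanus:1,(spelaeus:1,(arctos:1,maritimus:1):1):1);"
    elif branch_mode == "given_lengths":
        if divergence_times is None:
            raise ValueError("given_lengths mode needs divergence_times")
        t0 = float(divergence_times["root"])
        t1 = float(divergence_times["spelaeus_split"])
        t2 = float(divergence_times["arctos_maritimus"])
        if not t0 > t1 > t2 > 0:
            raise ValueError("divergence times must satisfy root > split > pair > 0")
        newick = (
            f"(americanus:{t0:g},(spelaeus:{t1:g},(arctos:{t2:g},"
            f"maritimus:{t2:g}):{t1 - t2:g}):{t0 - t1:g});"
        )
    else:
        raise ValueError("branch_mode must be 'unit_lengths' or 'given_lengths'")
    return read_newick(newick)


def _edge_weights(tree: PhyloTree, branch_mode: str) -> np.ndarray:
    """Per-node weight of the branch above it (index 0 = root, unused)."""
    if branch_mode == "unit_lengths":
        return np.ones(tree.n_nodes)
    if branch_mode != "given_lengths":
        raise ValueError("branch_mode must be 'given_lengths' or 'unit_lengths'")
    weights = tree.branch_lengths.copy()
    if np.isnan(weights[1:]).any():
        raise ValueError("given_lengths mode requires a length on every branch")
    return weights


def squared_change_length(tree: PhyloTree, tip_values: dict,
                          branch_mode: str = "unit_lengths"
                          ) -> tuple[float, np.ndarray]:
    """Minimum total squared change of tip data mapped onto the tree.

    ``tip_values`` maps tip label -> trait vector (or scalar).  Internal
    node values minimise sum over branches of ||child - parent||^2 / w,
    with w the branch length (``given_lengths``) or 1 (``unit_lengths``).
    Zero-length branches act as hard equality constraints.  Returns the
    minimised total (summed over trait dimensions) and the (n_nodes, q)
    matrix of node values.
    """
    missing = [lab for lab in tree.tip_labels if lab not in tip_values]
    if missing:
        raise ValueError(f"tip values missing for: {missing}")
    values = np.vstack([np.atleast_1d(np.asarray(tip_values[lab], dtype=float))
                        for lab in tree.tip_labels])
    q = values.shape[1]
    n = tree.n_nodes
    weights = _edge_weights(tree, branch_mode)
    # union-find contraction of zero-length branches (hard equality)
    rep = np.arange(n)

    def find(i: int) -> int:
        while rep[i] != i:
            rep[i] = rep[rep[i]]
            i = rep[i]
        return i

    for child in range(1, n):
        if weights[child] == 0:
            ra, rb = find(child), find(tree.parent[child])
            rep[ra] = rb
    groups = np.array([find(i) for i in range(n)])
    kept = np.unique(groups)
    remap = {g: i for i, g in enumerate(kept)}
    m = kept.size
    conductance = np.zeros((m, m))
    for child in range(1, n):
        if weights[child] == 0:
            continue
        a = remap[groups[child]]
        b = remap[groups[tree.parent[child]]]
        c = 1.0 / weights[child]
        conductance[a, b] += c
        conductance[b, a] += c
    laplacian = np.diag(conductance.sum(axis=1)) - conductance
    node_values = np.zeros((m, q))
    is_tip = np.zeros(m, dtype=bool)
    for t, tid in enumerate(tree.tip_ids):
        g = remap[groups[tid]]
        if is_tip[g] and not np.allclose(node_values[g], values[t]):
            raise ValueError(
                "zero-length branches force two tips with different values "
                "to coincide"
            )
        is_tip[g] = True
        node_values[g] = values[t]
    free = ~is_tip
    if free.any():
        lhs = laplacian[np.ix_(free, free)]
        rhs = -laplacian[np.ix_(free, is_tip)] @ node_values[is_tip]
        node_values[free] = np.linalg.solve(lhs, rhs)
    total = 0.0
    for child in range(1, n):
        if weights[child] == 0:
            continue
        a = remap[groups[child]]
        b = remap[groups[tree.parent[child]]]
        total += float(((node_values[a] - node_values[b]) ** 2).sum()) / weights[child]
    full = node_values[[remap[g] for g in groups]]
    return total, full


@dataclass
class SignalTestResult:
    observed_tree_length: float
    permutation_p: float
    n_permutations: int
    seed: int | None
    branch_mode: str
    exhaustive: bool = False
    null_lengths: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def phylo_signal_permutation(tree: PhyloTree, tip_values: dict,
                             n_permutations: int = 10000,
                             seed: int | None = None,
                             branch_mode: str = "unit_lengths"
                             ) -> SignalTestResult:
    """Permutation test of phylogenetic signal.

    The null hypothesis of no signal is simulated by randomly reassigning
    the tip trait vectors to the tips (vectors permuted jointly, preserving
    trait covariance); the p-value is the proportion of permutations whose
    tree length is at most the observed length.  With at most 8 tips all
    distinct permutations are enumerated (the identity among them, so p is
    never 0 and is exact); otherwise ``n_permutations`` random assignments
    are sampled with the add-one convention.
    """
    labels = tree.tip_labels
    values = [np.atleast_1d(np.asarray(tip_values[lab], dtype=float))
              for lab in labels]
    observed, _ = squared_change_length(tree, tip_values, branch_mode)
    t = len(labels)
    tol = 1e-12 * max(observed, 1.0)

    def length_for(order) -> float:
        assignment = {labels[i]: values[order[i]] for i in range(t)}
        length, _ = squared_change_length(tree, assignment, branch_mode)
        return length

    if t <= _ENUMERATION_LIMIT:
        null = np.array([length_for(order)
                         for order in _permutations(range(t))])
        p = float((null <= observed + tol).sum() / null.size)
        return SignalTestResult(
            observed_tree_length=observed,
            permutation_p=p,
            n_permutations=int(null.size),
            seed=seed,
            branch_mode=branch_mode,
            exhaustive=True,
            null_lengths=null,
        )
    rng = np.random.default_rng(seed)
    null = np.array([length_for(rng.permutation(t))
                     for _ in range(n_permutations)])
    p = (int((null <= observed + tol).sum()) + 1) / (n_permutations + 1)
    return SignalTestResult(
        observed_tree_length=observed,
        permutation_p=p,
        n_permutations=n_permutations,
        seed=seed,
        branch_mode=branch_mode,
        exhaustive=False,
        null_lengths=null,
    )
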