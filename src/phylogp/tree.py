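"""Rooted phylogenies with branch lengths.

Trees are stored as flat preorder arrays (root has id 0, every child id is
larger than its parent's), so that every matrix built downstream --
patristic distances, OU covariances, Gaussian posteriors -- can be indexed
by the same stable integer node ids.  Newick text is parsed with dendropy;
only the in-memory representation is our own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PatristicMatrix",
    "read_newick",
    "write_newick",
    "random_tree",
    "sample_subtree",
    "DEFAULT_BRANCH_DIST",
]

#: Default branch-length distribution: lognormal with mean ~0.12 and a heavy
#: right tail, a documented stand-in for typical gene-family trees.
DEFAULT_BRANCH_DIST = ("lognormal", {"mu": -2.62, "sigma": 1.0})


class Phylogeny:
    """A rooted tree with non-negative branch lengths and >= 2 tips.

    Parameters
    ----------
    parent : sequence of int
        ``parent[i]`` is the preorder id of node ``i``'s parent; the root
        (node 0) has parent ``-1``.  Preorder ordering requires
        ``parent[i] < i`` for every non-root node.
    branch_lengths : sequence of float
        Length of the edge above each node; the root's entry is 0.
    labels : sequence of str or None
        Node labels.  Every tip must carry a unique label; internal labels
        are optional and preserved through Newick round trips.
    """

    def __init__(self, parent, branch_lengths, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if n < 3:
            raise ValueError("a phylogeny needs at least 2 tips (3 nodes)")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("node 0 must be the unique root (parent -1)")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be numbered in preorder")
        if np.any(self.branch_lengths < 0) or not np.all(
            np.isfinite(self.branch_lengths)
        ):
            raise ValueError("branch lengths must be finite and non-negative")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        tips = [self.labels[i] for i in np.flatnonzero(self.is_tip)]
        if any(t is None for t in tips):
            raise ValueError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_ids(self) -> np.ndarray:
        """Preorder ids of tips, in preorder order."""
        return np.flatnonzero(self.is_tip)

    @property
    def internal_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.branch_lengths[i]
        return d

    def mrca(self, i: int, j: int) -> int:
        """Most recent common ancestor of nodes ``i`` and ``j``."""
        anc = set()
        a = i
        while a != -1:
            anc.add(a)
            a = int(self.parent[a]) if a else -1
        b = j
        while b not in anc:
            b = int(self.parent[b])
        return b

    @property
    def lmax(self) -> float:
        """Maximum patristic distance between two tips."""
        return self.patristic_matrix().lmax

    # -- distances -------------------------------------------------------
    def patristic_matrix(self, include_internal: bool = False) -> "PatristicMatrix":
        """Additive path-length distances between nodes.

        With ``include_internal`` the matrix covers all nodes in preorder;
        otherwise tips only (preorder order).
        """
        n = self.n_nodes
        depth = self.depths()
        # depth of the MRCA for every node pair, filled at the MRCA itself
        md = np.zeros((n, n))
        desc: list[np.ndarray | None] = [None] * n
        for i in range(n - 1, -1, -1):
            kids = self.children[i]
            if not kids:
                desc[i] = np.array([i])
                continue
            arrs = [desc[c] for c in kids]
            for a in range(len(arrs)):
                for b in range(a + 1, len(arrs)):
                    md[np.ix_(arrs[a], arrs[b])] = depth[i]
                    md[np.ix_(arrs[b], arrs[a])] = depth[i]
            below = np.concatenate(arrs)
            md[i, below] = depth[i]
            md[below, i] = depth[i]
            desc[i] = np.concatenate(([i], below))
        np.fill_diagonal(md, depth)
        dist = depth[:, None] + depth[None, :] - 2.0 * md
        np.fill_diagonal(dist, 0.0)
        if include_internal:
            ids = np.arange(n)
        else:
            ids = self.tip_ids
            dist = dist[np.ix_(ids, ids)]
        return PatristicMatrix(
            node_ids=ids,
            labels=[self.labels[i] for i in ids],
            dist=dist,
            is_tip=self.is_tip[ids].copy(),
        )

    # -- transforms ------------------------------------------------------
    def rescaled(self, lmax: float) -> "Phylogeny":
        """Return a copy with branch lengths scaled so the maximum tip-tip
        patristic distance equals ``lmax``."""
        cur = self.lmax
        if cur <= 0:
            raise ValueError("cannot rescale a tree with zero depth")
        return Phylogeny(
            self.parent, self.branch_lengths * (lmax / cur), self.labels
        )

    def induced_subtree(self, keep_labels) -> "Phylogeny":
        """Subtree induced by a set of tip labels.

        Unsampled lineages are pruned, degree-2 nodes are suppressed with
        branch lengths summed, and the new root is the MRCA of the kept
        tips; pairwise patristic distances among kept tips are preserved.
        """
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"unknown tip labels: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("an induced subtree needs at least 2 tips")
        # postorder fold: ret[i] = (record, length of path from i down to it)
        ret: list[tuple[dict, float] | None] = [None] * self.n_nodes
        for i in range(self.n_nodes - 1, -1, -1):
            if self.is_tip[i]:
                if self.labels[i] in keep:
                    ret[i] = ({"label": self.labels[i], "children": []}, 0.0)
                continue
            kept = [
                (ret[c][0], self.branch_lengths[c] + ret[c][1])
                for c in self.children[i]
                if ret[c] is not None
            ]
            if not kept:
                continue
            if len(kept) == 1:
                ret[i] = (kept[0][0], kept[0][1])
            else:
                ret[i] = ({"label": self.labels[i], "children": kept}, 0.0)
        root_rec = ret[0][0]
        # flatten to preorder arrays
        parent, lengths, labels = [-1], [0.0], [root_rec["label"]]
        stack = [(root_rec, 0)]
        while stack:
            rec, pid = stack.pop()
            for child, blen in reversed(rec["children"]):
                labels.append(child["label"])
                parent.append(pid)
                lengths.append(blen)
                stack.append((child, len(parent) - 1))
        return Phylogeny(parent, lengths, labels)

    # -- Newick ----------------------------------------------------------
    def to_newick(self) -> str:
        """Newick string with branch lengths on all non-root edges."""

        def fmt(i: int) -> str:
            lab = self.labels[i] if self.labels[i] is not None else ""
            if self.is_tip[i]:
                body = lab
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[i]) + ")" + lab
            if i == 0:
                return body
            return f"{body}:{format(self.branch_lengths[i], '.17g')}"

        return fmt(0) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


@dataclass
class PatristicMatrix:
    """Symmetric additive distances between an ordered set of nodes."""

    node_ids: np.ndarray
    labels: list
    dist: np.ndarray
    is_tip: np.ndarray

    @property
    def lmax(self) -> float:
        """Maximum distance between two tips."""
        tips = np.flatnonzero(self.is_tip)
        if tips.size < 2:
            raise ValueError("need at least two tips for lmax")
        sub = self.dist[np.ix_(tips, tips)]
        return float(sub.max())

    def tip_pair_percentile(self, q) -> float:
        """Percentile of the off-diagonal tip-tip distance distribution."""
        tips = np.flatnonzero(self.is_tip)
        sub = self.dist[np.ix_(tips, tips)]
        iu = np.triu_indices(len(tips), k=1)
        return float(np.percentile(sub[iu], q))


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a rooted Newick string into a :class:`Phylogeny`.

    Every non-root edge must carry a branch length unless
    ``default_branch_length`` is given; a missing root edge length is 0.
    Unlabelled internal nodes receive stable preorder integer ids.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick: {exc}") from exc
    parent, lengths, labels = [], [], []
    index: dict[int, int] = {}
    for nd in dt.preorder_node_iter():
        my_id = len(parent)
        index[id(nd)] = my_id
        if nd.parent_node is None:
            parent.append(-1)
            lengths.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            blen = nd.edge.length
            if blen is None:
                if default_branch_length is None:
                    raise ValueError(
                        "missing branch length on an edge and no default set"
                    )
                blen = default_branch_length
            lengths.append(float(blen))
        if nd.is_leaf():
            labels.append(nd.taxon.label if nd.taxon is not None else None)
        else:
            labels.append(nd.label)
    return Phylogeny(parent, lengths, labels)


def write_newick(tree: Phylogeny) -> str:
    """Serialize a :class:`Phylogeny` to Newick text."""
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Random trees and bagging support


def _branch_sampler(branch_dist):
    if isinstance(branch_dist, str):
        name, params = branch_dist, None
    else:
        name, params = branch_dist
    if name == "exponential":
        params = {"rate": 1.0 / 0.12} if params is None else params
        rate = float(params["rate"])
        return lambda rng, size: rng.exponential(1.0 / rate, size)
    if name == "lognormal":
        params = dict(DEFAULT_BRANCH_DIST[1]) if params is None else params
        mu, sigma = float(params["mu"]), float(params["sigma"])
        return lambda rng, size: rng.lognormal(mu, sigma, size)
    if name == "fixed":
        params = {"value": 0.12} if params is None else params
        value = float(params["value"])
        return lambda rng, size: np.full(size, value)
    raise ValueError(f"unsupported branch-length distribution: {name!r}")


def random_tree(
    n_tips: int,
    branch_dist=DEFAULT_BRANCH_DIST,
    seed=None,
    scale_lmax: float | None = None,
) -> Phylogeny:
    """Random binary topology (Yule splitting) with i.i.d. branch lengths.

    Parameters
    ----------
    n_tips : int
        Number of tips (>= 2).
    branch_dist : str or (str, dict)
        One of ``"exponential"`` (rate), ``"lognormal"`` (mu, sigma),
        ``"fixed"`` (value); parameters optional.
    seed : int, Generator or None
        Source of randomness; a fixed seed gives a bitwise-identical tree.
    scale_lmax : float, optional
        If given, rescale branch lengths so the maximum tip-tip patristic
        distance equals this value.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    sampler = _branch_sampler(branch_dist)
    rng = np.random.default_rng(seed)
    # grow a pure-birth topology: repeatedly split a uniformly chosen tip
    children: list[list[int]] = [[1, 2], [], []]
    leaves = [1, 2]
    while len(leaves) < n_tips:
        k = int(rng.integers(len(leaves)))
        node = leaves[k]
        a, b = len(children), len(children) + 1
        children[node] = [a, b]
        children.append([])
        children.append([])
        leaves[k] = a
        leaves.append(b)
    # renumber in preorder
    order, stack = [], [0]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(reversed(children[u]))
    newid = {old: i for i, old in enumerate(order)}
    parent = np.full(len(order), -1, dtype=np.int64)
    for old, kids in enumerate(children):
        for c in kids:
            parent[newid[c]] = newid[old]
    lengths = np.zeros(len(order))
    lengths[1:] = sampler(rng, len(order) - 1)
    labels: list[str | None] = [None] * len(order)
    tip_counter = 0
    for i in range(len(order)):
        if not children[order[i]]:
            tip_counter += 1
            labels[i] = f"t{tip_counter}"
    tree = Phylogeny(parent, lengths, labels)
    if scale_lmax is not None:
        tree = tree.rescaled(scale_lmax)
    return tree


def sample_subtree(tree: Phylogeny, k: int, seed=None) -> Phylogeny:
    """Induced subtree on ``k`` tips sampled uniformly without replacement.

    Patristic distances among the retained tips are preserved exactly.
    """
    n = tree.n_tips
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    labels = [tree.tip_labels[i] for i in idx]
    sub = tree.induced_subtree(labels)
    if sub.n_tips != k:  # pragma: no cover - defensive
        warnings.warn("induced subtree lost tips unexpectedly")
    return sub
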