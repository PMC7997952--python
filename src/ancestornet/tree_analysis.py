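"""Gene-tree analysis: MAD rooting, divergence, sister diversity, F81.

Unrooted maximum-likelihood gene trees carry no root; minimal ancestor
deviation (MAD) rooting places the root at the point of the tree that
minimises the root-mean-square relative deviation of induced
ancestor-descendant distances from the clocklike expectation. For every
leaf pair (b, c) and candidate root point rho, the induced ancestor is
the point where the paths from b and c towards the root meet, and the
pair's relative deviation is

    |2 * d(b, anc) / d(b, c) - 1|  ==  |d(b, rho) - d(c, rho)| / d(b, c).

The candidate position along each branch has a closed-form minimiser of
the sum of squared deviations, clamped to the branch. Trees whose best
and second-best branches score within a relative tolerance have an
ambiguous root and are discarded from downstream analyses.

Downstream of rooting, this module measures per-group root-to-tip
divergence (branch length and node depth, normalised per tree by the
largest distance), scores sister-clade taxonomic diversity of each
group's pure clades, and estimates discrete root states under the F81
substitution model with marginal-posterior prediction.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .metabolic_network import Reaction

logger = logging.getLogger(__name__)


@dataclass
class GeneTree:
    """An unrooted gene tree with genome-labelled leaves."""

    tree_id: str
    tree: dendropy.Tree
    family_id: str = ""


@dataclass
class RootInference:
    """One candidate root branch for a tree, with its MAD score."""

    root_branch: int
    split: frozenset[str]  # leaf labels on the child side of the branch
    root_position: float  # fraction along the branch, from the parent end
    mad_value: float
    ambiguity_index: float = 1.0
    is_ambiguous: bool = False


@dataclass
class DivergenceRecord:
    tree_id: str
    group: str
    metric: str
    normalized_distance: float
    representative_genome: str


@dataclass
class SisterDiversityRecord:
    tree_id: str
    group: str
    score: int
    pure_clade_count: int


@dataclass
class RootStateEstimate:
    tree_id: str
    trait: str
    posterior: dict[str, float]
    predicted_state: str
    predicted_states: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# unrooted tree arrays


class _UnrootedArrays:
    """Index-based view of an unrooted tree.

    A bifurcating seed node (an artifact of rooted Newick) is collapsed
    so that its two incident branches become one, making the analysis
    invariant under the input's arbitrary rooting.
    """

    def __init__(self, tree: dendropy.Tree):
        seed = tree.seed_node
        dnodes = list(tree.preorder_node_iter())
        merge_seed = len(seed.child_nodes()) == 2 and len(dnodes) > 3
        nodes = [nd for nd in dnodes if not (merge_seed and nd is seed)]
        index = {id(nd): i for i, nd in enumerate(nodes)}
        adj: list[list[tuple[int, float]]] = [[] for _ in nodes]

        def _len(e) -> float:
            v = e.length
            if v is None:
                return 0.0
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"invalid branch length {v}")
            return float(v)

        if merge_seed:
            c1, c2 = seed.child_nodes()
            i, j = index[id(c1)], index[id(c2)]
            t = _len(c1.edge) + _len(c2.edge)
            adj[i].append((j, t))
            adj[j].append((i, t))
        for nd in nodes:
            for ch in nd.child_nodes():
                if merge_seed and nd is seed:
                    continue
                i, j = index[id(nd)], index[id(ch)]
                t = _len(ch.edge)
                adj[i].append((j, t))
                adj[j].append((i, t))

        labels: dict[int, str] = {}
        for nd in nodes:
            if nd.is_leaf():
                lbl = nd.taxon.label if nd.taxon else nd.label
                if lbl is None:
                    raise ValueError("unlabeled leaf")
                labels[index[id(nd)]] = lbl
        if len(set(labels.values())) != len(labels):
            raise ValueError("duplicate leaf labels")

        self.n_nodes = len(nodes)
        self.adj = adj
        self.leaf_idx = sorted(labels)
        self.leaf_labels = [labels[i] for i in self.leaf_idx]

        # orientation: DFS from node 0 gives each edge a (parent, child)
        parent = [-1] * self.n_nodes
        plen = [0.0] * self.n_nodes
        order = [0]
        seen = [False] * self.n_nodes
        seen[0] = True
        stack = [0]
        while stack:
            u = stack.pop()
            for v, t in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    parent[v] = u
                    plen[v] = t
                    order.append(v)
                    stack.append(v)
        self.parent = parent
        self.parent_len = plen
        self.order = order  # preorder from node 0
        # edges as (parent, child, length), child identifies the edge
        self.edges = [
            (parent[v], v, plen[v]) for v in order if parent[v] != -1
        ]

        # leaf-to-node distances, shape (L, n_nodes)
        L = len(self.leaf_idx)
        dist = np.zeros((L, self.n_nodes))
        for k, leaf in enumerate(self.leaf_idx):
            d = dist[k]
            seen2 = [False] * self.n_nodes
            seen2[leaf] = True
            stack = [leaf]
            while stack:
                u = stack.pop()
                for v, t in adj[u]:
                    if not seen2[v]:
                        seen2[v] = True
                        d[v] = d[u] + t
                        stack.append(v)
        self.leaf_node_dist = dist
        self.leaf_pair_dist = dist[:, self.leaf_idx]

        # boolean leaf masks of the child-side subtree of each node
        pos_of_leaf = {leaf: k for k, leaf in enumerate(self.leaf_idx)}
        masks = np.zeros((self.n_nodes, L), dtype=bool)
        for v in reversed(order):
            if v in pos_of_leaf:
                masks[v, pos_of_leaf[v]] = True
            if parent[v] != -1:
                masks[parent[v]] |= masks[v]
        self.subtree_leaf_mask = masks


# ---------------------------------------------------------------------------
# MAD rooting


def mad_root(
    tree: dendropy.Tree, tie_tol: float = 1e-6
) -> list[RootInference]:
    """Score every branch as a root candidate; best (lowest MAD) first.

    ``is_ambiguous`` is set on all entries when at least two branches
    match the minimum MAD within relative tolerance ``tie_tol``.
    Leaf pairs at zero path distance are skipped (their relative
    deviation is undefined).
    """
    arr = _UnrootedArrays(tree)
    L = len(arr.leaf_idx)
    if L < 3:
        raise ValueError("rooting needs at least 3 leaves")
    D = arr.leaf_pair_dist
    if D.max() == 0.0:
        raise ValueError("degenerate tree: all branch lengths zero")
    valid = D > 0.0
    iu = np.triu_indices(L, k=1)
    n_pairs = int(valid[iu].sum())

    results = []
    for branch_id, (u, v, t) in enumerate(arr.edges):
        bmask = arr.subtree_leaf_mask[v]
        amask = ~bmask
        dA = arr.leaf_node_dist[amask, u]
        dB = arr.leaf_node_dist[bmask, v]

        # cross pairs: deviation ((dA + t - dB) - 2x) / dbc at position
        # x from the child end; quadratic in x with closed-form minimum
        dbc = dA[:, None] + t + dB[None, :]
        ok = dbc > 0.0
        num0 = dA[:, None] + t - dB[None, :]
        w = np.zeros_like(dbc)
        w[ok] = 1.0 / dbc[ok] ** 2
        denom = 2.0 * w.sum()
        if denom > 0.0 and t > 0.0:
            x = float(np.clip((num0 * w).sum() / denom, 0.0, t))
        else:
            x = 0.0
        sq = float((((num0 - 2.0 * x) ** 2) * w).sum())

        # same-side pairs: deviation fixed given the root's side
        for mask, dref in ((amask, u), ((bmask), v)):
            idx = np.flatnonzero(mask)
            if len(idx) < 2:
                continue
            dd = arr.leaf_node_dist[idx, dref]
            sub = D[np.ix_(idx, idx)]
            diff = dd[:, None] - dd[None, :]
            okk = sub > 0.0
            r = np.zeros_like(sub)
            r[okk] = diff[okk] / sub[okk]
            sq += float((r**2).sum()) / 2.0

        mad = math.sqrt(sq / n_pairs) if n_pairs else float("nan")
        pos = (t - x) / t if t > 0.0 else 0.5
        results.append(
            RootInference(
                root_branch=branch_id,
                split=frozenset(
                    lbl for lbl, m in zip(arr.leaf_labels, bmask) if m
                ),
                root_position=pos,
                mad_value=mad,
            )
        )
    results.sort(key=lambda r: (r.mad_value, r.root_branch))
    best = results[0].mad_value
    second = results[1].mad_value if len(results) > 1 else float("inf")
    ai = best / second if second > 0 else 1.0
    ambiguous = second <= best * (1.0 + tie_tol)
    for r in results:
        r.ambiguity_index = ai
        r.is_ambiguous = ambiguous
    return results


def filter_ambiguous(
    inferences: Mapping[str, Sequence[RootInference]],
) -> tuple[dict[str, RootInference], dict[str, int]]:
    """Keep only trees with a single admissible MAD root.

    Returns the best inference per retained tree and a count summary.
    """
    kept = {
        tid: infs[0]
        for tid, infs in inferences.items()
        if infs and not infs[0].is_ambiguous
    }
    counts = {
        "input": len(inferences),
        "ambiguous": len(inferences) - len(kept),
        "retained": len(kept),
    }
    logger.info(
        "root filtering: %(input)d trees, %(ambiguous)d ambiguous, "
        "%(retained)d retained", counts,
    )
    return kept, counts


# ---------------------------------------------------------------------------
# rooted tree structure


class RootedTree:
    """Lightweight rooted tree: parent/children arrays plus leaf labels.

    Node 0 is the root. ``labels[i]`` is None for internal nodes.
    """

    def __init__(
        self,
        parent: list[int],
        lengths: list[float],
        labels: list[str | None],
    ):
        self.parent = parent
        self.lengths = lengths
        self.labels = labels
        self.children: list[list[int]] = [[] for _ in parent]
        for i, p in enumerate(parent):
            if p >= 0:
                self.children[p].append(i)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def leaves(self) -> list[int]:
        return [i for i, lbl in enumerate(self.labels) if lbl is not None]

    def preorder(self) -> list[int]:
        out, stack = [], [0]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(reversed(self.children[u]))
        return out

    def postorder(self) -> list[int]:
        return list(reversed(self.preorder()))

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                s = self.labels[i] or ""
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if self.parent[i] >= 0:
                s += f":{self.lengths[i]:.10g}"
            return s

        return rec(0) + ";"

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            preserve_underscores=True,
        )

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "RootedTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        for nd in nodes:
            p = nd.parent_node
            parent.append(index[id(p)] if p is not None else -1)
            lengths.append(float(nd.edge.length or 0.0))
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else nd.label)
            else:
                labels.append(None)
        return cls(parent, lengths, labels)


def apply_root(
    tree: dendropy.Tree, inference: RootInference
) -> RootedTree:
    """Build the rooted tree implied by a MAD root inference."""
    arr = _UnrootedArrays(tree)
    u, v, t = arr.edges[inference.root_branch]
    # distance from the parent endpoint u to the root point
    du = inference.root_position * t

    parent: list[int] = [-1]
    lengths: list[float] = [0.0]
    labels: list[str | None] = [None]
    leaf_label = dict(zip(arr.leaf_idx, arr.leaf_labels))

    def hang(node: int, avoid: int, par: int, plen: float) -> None:
        idx = len(parent)
        parent.append(par)
        lengths.append(plen)
        labels.append(leaf_label.get(node))
        for nbr, w in arr.adj[node]:
            if nbr != avoid:
                hang(nbr, node, idx, w)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, arr.n_nodes * 4 + 100))
    try:
        hang(v, u, 0, t - du)
        hang(u, v, 0, du)
    finally:
        sys.setrecursionlimit(old)
    return RootedTree(parent, lengths, labels)


def mad_root_tree(
    tree: dendropy.Tree, tie_tol: float = 1e-6
) -> tuple[RootedTree, list[RootInference]]:
    """Convenience wrapper: MAD-root a tree, returning the rooted tree
    and all scored candidates (best first)."""
    inferences = mad_root(tree, tie_tol)
    return apply_root(tree, inferences[0]), inferences


# ---------------------------------------------------------------------------
# divergence


def root_to_tip(rooted: RootedTree, metric: str) -> dict[str, float]:
    """Normalised root-to-tip distances, one per leaf label.

    ``branch_length`` sums branch lengths along the root-to-leaf path
    (phenetic distance); ``node_depth`` counts branching events, i.e.
    edges, on the path (the root's initial split contributes one).
    Values are divided by the per-tree maximum, so the most divergent
    leaf scores exactly 1.
    """
    if metric not in ("branch_length", "node_depth"):
        raise ValueError(f"unknown metric {metric!r}")
    acc = np.zeros(rooted.n_nodes)
    for i in rooted.preorder():
        p = rooted.parent[i]
        if p >= 0:
            step = rooted.lengths[i] if metric == "branch_length" else 1.0
            acc[i] = acc[p] + step
    leaves = rooted.leaves()
    mx = max(acc[i] for i in leaves)
    if mx == 0.0:
        raise ValueError("zero maximum root-to-tip distance")
    return {rooted.labels[i]: float(acc[i] / mx) for i in leaves}


def group_divergence(
    distance_tables: Mapping[str, Mapping[str, float]],
    genome_groups: Mapping[str, str],
    metric: str = "branch_length",
) -> tuple[list[DivergenceRecord], dict[str, float]]:
    """Per-tree per-group minimum distances and per-group means.

    Each group is represented in each tree by its least divergent
    genome; groups absent from a tree contribute no record there, and
    the across-tree mean for a group averages only the trees where it
    occurs.
    """
    records: list[DivergenceRecord] = []
    sums: dict[str, float] = defaultdict(float)
    n: dict[str, int] = defaultdict(int)
    for tid in sorted(distance_tables):
        table = distance_tables[tid]
        best: dict[str, tuple[float, str]] = {}
        for leaf, dist in table.items():
            grp = genome_groups.get(leaf)
            if grp is None:
                continue
            if grp not in best or (dist, leaf) < best[grp]:
                best[grp] = (dist, leaf)
        for grp in sorted(best):
            dist, leaf = best[grp]
            records.append(
                DivergenceRecord(tid, grp, metric, dist, leaf)
            )
            sums[grp] += dist
            n[grp] += 1
    means = {g: sums[g] / n[g] for g in sums}
    return records, means


# ---------------------------------------------------------------------------
# sister diversity


def sister_diversity(
    rooted: RootedTree,
    group: str,
    leaf_groups: Mapping[str, str],
) -> SisterDiversityRecord | None:
    """Maximal sister-clade diversity over a group's pure clades.

    A pure clade is a maximal subtree whose leaves all belong to
    ``group``; its sister is the union of the other children of its
    parent. The record's score is the largest number of distinct other
    group labels found in any sister. Returns None when the group is
    absent, or when the whole tree is one pure clade (no sister
    exists).
    """
    n = rooted.n_nodes
    groups_below: list[set[str]] = [set() for _ in range(n)]
    pure: list[bool] = [False] * n
    for i in rooted.postorder():
        lbl = rooted.labels[i]
        if lbl is not None:
            g = leaf_groups.get(lbl)
            if g is None:
                raise KeyError(f"leaf {lbl!r} has no group label")
            groups_below[i] = {g}
            pure[i] = g == group
        else:
            for c in rooted.children[i]:
                groups_below[i] |= groups_below[c]
            pure[i] = groups_below[i] == {group}
    if group not in groups_below[0]:
        return None

    scores = []
    n_pure = 0
    for i in range(n):
        p = rooted.parent[i]
        if pure[i] and (p < 0 or not pure[p]):
            n_pure += 1
            if p < 0:
                continue  # the whole tree is pure: no sister clade
            sister: set[str] = set()
            for sib in rooted.children[p]:
                if sib != i:
                    sister |= groups_below[sib]
            sister.discard(group)
            if sister:
                scores.append(len(sister))
    if not scores:
        return None
    return SisterDiversityRecord("", group, max(scores), n_pure)


def sister_diversity_all_groups(
    rooted: RootedTree,
    leaf_groups: Mapping[str, str],
    tree_id: str = "",
) -> list[SisterDiversityRecord]:
    """Sister-diversity records for every group present in the tree."""
    present = sorted({leaf_groups[l] for l in (
        rooted.labels[i] for i in rooted.leaves())})
    out = []
    for g in present:
        rec = sister_diversity(rooted, g, leaf_groups)
        if rec is not None:
            rec.tree_id = tree_id
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# F81 ancestral root state


def _f81_matrix(pi: np.ndarray, t: float) -> np.ndarray:
    s = float((pi**2).sum())
    if s >= 1.0:  # single possible state
        return np.eye(len(pi))
    beta = 1.0 / (1.0 - s)
    e = math.exp(-beta * t)
    return e * np.eye(len(pi)) + (1.0 - e) * pi[None, :]


def f81_root_posterior(
    rooted: RootedTree,
    tip_states: Mapping[str, str],
    states: Sequence[str],
    freqs: str | Mapping[str, float] = "empirical",
    tree_id: str = "",
    trait: str = "trait",
) -> RootStateEstimate:
    """Marginal posterior of the root state under the F81 model.

    Tips absent from ``tip_states`` (or mapped to None/"") are treated
    as unknown and contribute flat partial likelihoods. Equilibrium
    frequencies are empirical pooled tip frequencies by default, or
    uniform, or user-supplied. The prediction is the maximum-posterior
    state; states whose posterior is within a factor of two of the
    maximum are co-reported, approximating marginal-posterior state-set
    selection.
    """
    states = list(states)
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    observed = [
        s for s in tip_states.values() if s not in (None, "")
    ]
    if not observed:
        raise ValueError("no known tip states")
    for s in observed:
        if s not in sidx:
            raise ValueError(f"state {s!r} not in declared state set")

    if freqs == "empirical":
        counts = Counter(observed)
        pi = np.array([counts.get(s, 0) for s in states], dtype=float)
        pi /= pi.sum()
    elif freqs == "uniform":
        pi = np.full(k, 1.0 / k)
    else:
        pi = np.array([float(freqs[s]) for s in states])
        pi /= pi.sum()

    partial = np.ones((rooted.n_nodes, k))
    for i in rooted.postorder():
        lbl = rooted.labels[i]
        if lbl is not None:
            st = tip_states.get(lbl)
            if st not in (None, ""):
                partial[i] = 0.0
                partial[i][sidx[st]] = 1.0
        else:
            for c in rooted.children[i]:
                p = _f81_matrix(pi, rooted.lengths[c])
                partial[i] *= p @ partial[c]
            m = partial[i].max()
            if m > 0:  # scale against underflow
                partial[i] /= m
    post = pi * partial[0]
    total = post.sum()
    if total == 0.0:
        raise ValueError("zero likelihood at root")
    post /= total
    posterior = {s: float(post[sidx[s]]) for s in states}
    top = max(posterior.values())
    predicted = min(s for s, p in posterior.items() if p == top)
    co = tuple(
        s for s, p in sorted(posterior.items()) if p >= top / 2.0
    )
    return RootStateEstimate(
        tree_id, trait, posterior, predicted, co
    )


def aggregate_root_states(
    estimates: Sequence[RootStateEstimate],
) -> tuple[dict[str, float], list[str]]:
    """Across-tree frequency of predicted root states and the mode(s)."""
    if not estimates:
        raise ValueError("no estimates to aggregate")
    counts = Counter(e.predicted_state for e in estimates)
    total = sum(counts.values())
    freq = {s: c / total for s, c in sorted(counts.items())}
    top = max(counts.values())
    modal = sorted(s for s, c in counts.items() if c == top)
    return freq, modal


# ---------------------------------------------------------------------------
# verticality


def annotate_verticality(
    reaction: Reaction,
    family_verticality: Mapping[str, float],
) -> float | None:
    """Mean verticality over a reaction's encoding families.

    Families without a verticality entry are skipped (logged); a
    reaction with no scored family at all yields None.
    """
    vals = []
    for fam in sorted(reaction.encoding_families):
        if fam in family_verticality:
            vals.append(float(family_verticality[fam]))
        else:
            logger.debug(
                "reaction %s: family %s has no verticality entry",
                reaction.reaction_id, fam,
            )
    if not vals:
        logger.warning(
            "reaction %s: verticality undefined (no scored families)",
            reaction.reaction_id,
        )
        return None
    return float(np.mean(vals))
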