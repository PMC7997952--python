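"""Seeded generators for every input the pipeline consumes.

The generators plant a known ground truth — a similarity-graph
partition, a minimal completing reaction set, an earliest-diverging
("basal") taxonomic group, a root trait state — so that each analysis
stage can be tested for parameter recovery, not just for running.

The species history is a pure-birth (Yule) tree over genomes, made
ultrametric, with the basal group grafted directly at the root: the
basal split is therefore unambiguous and is the planted truth the
rooting, divergence and sister-diversity analyses should recover. Gene
trees are the species history after per-genome loss, optional lateral
transfers (subtree prune-regraft moves), and multiplicative lognormal
branch-rate noise. Discrete root traits evolve down the species history
under a constant switch rate.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expansion_reduction import TargetSet
from .genomes_families import SimilarityEdge
from .metabolic_network import Reaction
from .tree_analysis import RootedTree


@dataclass
class SyntheticWorld:
    """A species history plus the parameters all inputs derive from."""

    seed: int
    group_sizes: Mapping[str, int]  # group label -> genome count
    basal_group: str
    species_tree: RootedTree
    genome_groups: dict[str, str]
    lgt_rate: float = 0.0  # expected transfers per gene-tree branch
    loss_prob: float = 0.0
    rate_noise_sd: float = 0.0
    trait_states: tuple[str, ...] = ("rod", "coccus")
    root_state: str = "rod"
    trait_switch_rate: float = 0.05
    tip_states: dict[str, str] = field(default_factory=dict)

    @property
    def genomes(self) -> list[str]:
        return sorted(self.genome_groups)


# ---------------------------------------------------------------------------
# species history


def _yule_tree(
    labels: Sequence[str], rng: np.random.Generator
) -> tuple[list[int], list[float], list[str | None]]:
    """Ultrametric pure-birth tree, total height 1, as parent arrays.

    A random active tip splits at each of n-1 increasing times (the
    root at time 0); surviving tips terminate at height 1.
    """
    n = len(labels)
    if n == 1:
        return [-1], [0.0], [labels[0]]
    parent = [-1]
    node_labels: list[str | None] = [None]
    split = [1.0]  # split time of internals, 1.0 until a node splits
    active = [0]
    if n > 2:
        times = np.concatenate(
            [[0.0], np.sort(rng.uniform(0.1, 0.9, size=n - 2))]
        )
    else:
        times = np.array([0.0])
    for t in times:
        i = active.pop(int(rng.integers(len(active))))
        split[i] = float(t)
        for _ in range(2):
            parent.append(i)
            node_labels.append(None)
            split.append(1.0)
            active.append(len(parent) - 1)
    perm = rng.permutation(n)
    for k, i in enumerate(active):
        node_labels[i] = labels[perm[k]]
    lengths = [0.0] + [
        split[i] - split[parent[i]] for i in range(1, len(parent))
    ]
    return parent, lengths, node_labels


def simulate_world(
    seed: int,
    n_groups: int = 8,
    genomes_per_group: int = 2,
    lgt_rate: float = 0.0,
    loss_prob: float = 0.0,
    rate_noise_sd: float = 0.0,
    basal_stem: float = 0.3,
    trait_switch_rate: float = 0.05,
) -> SyntheticWorld:
    """Build a species history with a basal group grafted at the root."""
    if n_groups < 2 or genomes_per_group < 1:
        raise ValueError("need >=2 groups and >=1 genome per group")
    rng = np.random.default_rng(seed)
    groups = [f"G{k:02d}" for k in range(n_groups)]
    basal = groups[0]
    genome_groups = {}
    for g in groups:
        for j in range(genomes_per_group):
            genome_groups[f"{g}_g{j}"] = g

    crown_labels = [
        gid for gid, g in sorted(genome_groups.items()) if g != basal
    ]
    basal_labels = [
        gid for gid, g in sorted(genome_groups.items()) if g == basal
    ]

    cp, cl, clab = _yule_tree(crown_labels, rng)
    # root (0) has two children: the basal clade and the crown clade,
    # both reaching total height 1 + basal_stem from the root
    parent = [-1]
    lengths = [0.0]
    labels: list[str | None] = [None]

    def graft(p_arr, l_arr, lab_arr, stem: float) -> None:
        offset = len(parent)
        for i in range(len(p_arr)):
            p = p_arr[i]
            parent.append(0 if p == -1 else p + offset)
            lengths.append(stem if p == -1 else l_arr[i])
            labels.append(lab_arr[i])

    if len(basal_labels) == 1:
        parent.append(0)
        lengths.append(1.0 + basal_stem)
        labels.append(basal_labels[0])
    else:
        bp, bl, blab = _yule_tree(basal_labels, rng)
        graft(bp, bl, blab, basal_stem)
    graft(cp, cl, clab, basal_stem)
    species = RootedTree(parent, lengths, labels)

    # trait states evolve down the species tree at a constant rate
    states = ("rod", "coccus")
    root_state = states[0]
    node_state = {0: root_state}
    pre = species.preorder()
    for i in pre[1:]:
        s = node_state[species.parent[i]]
        n_switch = rng.poisson(trait_switch_rate * species.lengths[i])
        if n_switch % 2 == 1:
            s = states[1 - states.index(s)]
        node_state[i] = s
    tip_states = {
        species.labels[i]: node_state[i] for i in species.leaves()
    }
    return SyntheticWorld(
        seed=seed,
        group_sizes={g: genomes_per_group for g in groups},
        basal_group=basal,
        species_tree=species,
        genome_groups=genome_groups,
        lgt_rate=lgt_rate,
        loss_prob=loss_prob,
        rate_noise_sd=rate_noise_sd,
        trait_states=states,
        root_state=root_state,
        trait_switch_rate=trait_switch_rate,
        tip_states=tip_states,
    )


# ---------------------------------------------------------------------------
# gene trees


def _prune_to(
    tree: RootedTree, keep: set[str]
) -> RootedTree | None:
    """Restriction of a rooted tree to a leaf subset, suppressing
    unary nodes (their lengths add) and collapsing the root."""
    n = tree.n_nodes
    keep_node = [False] * n
    for i in tree.postorder():
        lbl = tree.labels[i]
        if lbl is not None:
            keep_node[i] = lbl in keep
        else:
            keep_node[i] = any(keep_node[c] for c in tree.children[i])
    if not keep_node[0]:
        return None

    parent: list[int] = []
    lengths: list[float] = []
    labels: list[str | None] = []

    def build(i: int, extra: float, par: int) -> None:
        kids = [c for c in tree.children[i] if keep_node[c]]
        if tree.labels[i] is None and len(kids) == 1:
            c = kids[0]
            build(c, extra + tree.lengths[c], par)
            return
        idx = len(parent)
        parent.append(par)
        lengths.append(extra)
        labels.append(tree.labels[i])
        for c in kids:
            build(c, tree.lengths[c], idx)

    build(0, 0.0, -1)
    rt = RootedTree(parent, lengths, labels)
    # a rooted tree must branch at the root; a single-child root means
    # the subtree below is the whole tree
    while len(rt.children[0]) == 1 and rt.labels[0] is None:
        # re-root at the single child
        sub = rt.children[0][0]
        mapping = {}
        np_, nl, nlab = [], [], []

        def copy(i: int, par: int) -> None:
            idx = len(np_)
            np_.append(par)
            nl.append(rt.lengths[i] if par >= 0 else 0.0)
            nlab.append(rt.labels[i])
            for c in rt.children[i]:
                copy(c, idx)

        copy(sub, -1)
        rt = RootedTree(np_, nl, nlab)
    return rt


def _rebuild(
    parent: list[int], lengths: list[float], labels: list[str | None]
) -> RootedTree:
    """Compact a parent array into a RootedTree, suppressing unary
    internal nodes (their edge lengths add) including a unary root."""
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    root = 0
    for i, p in enumerate(parent):
        if p == -1:
            root = i
        else:
            children[p].append(i)
    while labels[root] is None and len(children[root]) == 1:
        root = children[root][0]

    np_: list[int] = []
    nl: list[float] = []
    nlab: list[str | None] = []

    def build(i: int, extra: float, par: int) -> None:
        kids = children[i]
        if labels[i] is None and len(kids) == 1 and par != -1:
            build(kids[0], extra + lengths[kids[0]], par)
            return
        idx = len(np_)
        np_.append(par)
        nl.append(extra)
        nlab.append(labels[i])
        for c in kids:
            build(c, lengths[c], idx)

    build(root, 0.0, -1)
    return RootedTree(np_, nl, nlab)


def _spr(tree: RootedTree, rng: np.random.Generator) -> RootedTree:
    """One random subtree prune-regraft move.

    The pruned subtree keeps its branch lengths and reattaches at the
    midpoint of the recipient branch; a lineage thereby adopts the
    recipient's position in the tree, emulating a lateral transfer.
    Returns the tree unchanged when no valid move exists.
    """
    n = tree.n_nodes
    non_root = list(range(1, n))
    if len(non_root) < 3:
        return tree
    donor = int(rng.choice(non_root))
    under = set()
    stack = [donor]
    while stack:
        u = stack.pop()
        under.add(u)
        stack.extend(tree.children[u])
    recips = [i for i in non_root if i not in under and i != donor]
    if not recips:
        return tree
    recip = int(rng.choice(recips))

    parent = list(tree.parent)
    lengths = list(tree.lengths)
    labels = list(tree.labels)
    # new node splits the recipient edge at its midpoint
    new = len(parent)
    parent.append(parent[recip])
    lengths.append(lengths[recip] / 2.0)
    labels.append(None)
    parent[recip] = new
    lengths[recip] = lengths[recip] / 2.0
    parent[donor] = new
    return _rebuild(parent, lengths, labels)


def simulate_gene_trees(
    world: SyntheticWorld, n_trees: int, seed: int | None = None
) -> tuple[list[RootedTree], list[dict]]:
    """Gene trees derived from the species history.

    Each tree is the species tree restricted to the genomes that kept
    the gene (loss is i.i.d. Bernoulli per genome), reshuffled by a
    Poisson number of prune-regraft transfers, with branch lengths
    multiplied by i.i.d. lognormal(0, rate_noise_sd) noise. Trees
    reduced below 3 leaves are regenerated (counted in the event log).
    Returns the trees and a per-tree event log with transfer counts.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(
        world.seed + 1 if seed is None else seed
    )
    genomes = world.genomes
    trees: list[RootedTree] = []
    log: list[dict] = []
    while len(trees) < n_trees:
        keep = {
            g for g in genomes if rng.random() >= world.loss_prob
        }
        gt = _prune_to(world.species_tree, keep)
        if gt is None or len(gt.leaves()) < 3:
            log.append({"regenerated": True, "n_transfers": 0})
            continue
        n_branches = gt.n_nodes - 1
        n_transfers = int(rng.poisson(world.lgt_rate * n_branches))
        for _ in range(n_transfers):
            gt = _spr(gt, rng)
        if world.rate_noise_sd > 0.0:
            noise = rng.lognormal(
                0.0, world.rate_noise_sd, size=gt.n_nodes
            )
            gt = RootedTree(
                list(gt.parent),
                [
                    l * float(z) if p >= 0 else 0.0
                    for l, z, p in zip(gt.lengths, noise, gt.parent)
                ],
                list(gt.labels),
            )
        trees.append(gt)
        log.append(
            {"regenerated": False, "n_transfers": n_transfers,
             "n_leaves": len(gt.leaves())}
        )
    return trees, log


# ---------------------------------------------------------------------------
# reaction universe with a planted minimal completing set


def simulate_reaction_universe(
    n_core: int = 8,
    n_candidates: int = 12,
    n_targets: int = 10,
    planted_set_size: int = 4,
    seed: int = 0,
) -> tuple[list[Reaction], list[Reaction], TargetSet,
           dict[str, int], set[str]]:
    """A core chain plus candidates with a planted completing set.

    The core is a connected chain from an external seed compound that
    produces the first ``n_targets - planted_set_size`` targets. Each
    planted candidate is the only reaction in the universe producing
    one of the remaining targets; decoy candidates interconvert
    non-target byproducts and are therefore always removable. Scores
    (taxonomic group counts) are high for core-like and planted
    reactions and low for decoys, mirroring how broadly distributed
    reactions score in the real analysis.
    """
    if planted_set_size > n_candidates:
        raise ValueError("planted_set_size exceeds n_candidates")
    if planted_set_size > n_targets:
        raise ValueError("planted_set_size exceeds n_targets")
    if n_core < 1:
        raise ValueError("need at least one core reaction")
    rng = np.random.default_rng(seed)
    targets = [f"T{k:02d}" for k in range(n_targets)]
    n_core_targets = n_targets - planted_set_size
    core: list[Reaction] = []
    chain = ["X00"] + [f"X{k:02d}" for k in range(1, n_core + 1)]
    for k in range(n_core):
        prods = {chain[k + 1]: 1}
        # distribute the core-produced targets along the chain
        for j in range(n_core_targets):
            if j % n_core == k:
                prods[targets[j]] = 1
        core.append(
            Reaction(f"CORE{k:02d}", {chain[k]: 1}, prods,
                     reversible=bool(rng.random() < 0.3))
        )
    planted_targets = targets[n_core_targets:]
    candidates: list[Reaction] = []
    planted: set[str] = set()
    for j, tgt in enumerate(planted_targets):
        rid = f"PLNT{j:02d}"
        planted.add(rid)
        sub = chain[int(rng.integers(1, len(chain)))]
        candidates.append(
            Reaction(rid, {sub: 1}, {tgt: 1},
                     encoding_families={f"famP{j}"})
        )
    for j in range(n_candidates - planted_set_size):
        sub = chain[int(rng.integers(1, len(chain)))]
        candidates.append(
            Reaction(
                f"DECY{j:02d}", {sub: 1}, {f"Y{j:02d}": 1},
                reversible=bool(rng.random() < 0.3),
                encoding_families={f"famD{j}"},
            )
        )
    scores = {r.reaction_id: 25 for r in core}
    for r in candidates:
        if r.reaction_id in planted:
            scores[r.reaction_id] = int(rng.integers(10, 20))
        else:
            scores[r.reaction_id] = int(rng.integers(1, 10))
    target_set = TargetSet(
        {t: ("amino acid" if k < 20 else "cofactor")
         for k, t in enumerate(targets)}
    )
    return core, candidates, target_set, scores, planted


# ---------------------------------------------------------------------------
# similarity graphs and presence matrices


def simulate_similarity_graph(
    cluster_sizes: Sequence[int],
    p_in: float = 0.9,
    p_out: float = 0.05,
    identity_in_mean: float = 60.0,
    identity_out_mean: float = 15.0,
    seed: int = 0,
) -> tuple[list[SimilarityEdge], dict[str, int]]:
    """Planted-partition similarity edge list.

    Within-cluster pairs get an edge with probability ``p_in`` and
    identity ~ Normal(identity_in_mean, 5); between-cluster pairs with
    ``p_out`` and Normal(identity_out_mean, 5), both clipped to
    [0, 100]. E-values are set consistently below (within) or above
    (between) the 1e-10 threshold whenever the identity falls on the
    corresponding side of 25%. Returns the edges and the planted
    partition (sequence id -> cluster index).
    """
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    partition: dict[str, int] = {}
    for c, size in enumerate(cluster_sizes):
        for j in range(size):
            sid = f"s{c}_{j}"
            seqs.append(sid)
            partition[sid] = c
    edges: list[SimilarityEdge] = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            same = partition[seqs[i]] == partition[seqs[j]]
            p, mu = (p_in, identity_in_mean) if same else (
                p_out, identity_out_mean)
            if rng.random() < p:
                ident = float(np.clip(rng.normal(mu, 5.0), 0.0, 100.0))
                e = 10 ** float(rng.uniform(-60, -15)) if ident >= 25 \
                    else 10 ** float(rng.uniform(-8, -1))
                edges.append(
                    SimilarityEdge(seqs[i], seqs[j], ident, e)
                )
    return edges, partition


def simulate_presence_matrix(
    n_families: int,
    groups: Mapping[str, int],
    presence_profile: Mapping[str, float] | float = 0.5,
    n_universal: int = 0,
    seed: int = 0,
):
    """Random presence matrix with planted universal families.

    Each ordinary family's per-group genome presence is Bernoulli with
    the profile probability; the first ``n_universal`` families are
    planted present in every genome of every group.
    """
    from .genomes_families import PresenceMatrix
    import pandas as pd

    rng = np.random.default_rng(seed)
    glabels = sorted(groups)
    sizes = pd.Series({g: int(groups[g]) for g in glabels})
    rows = []
    fids = []
    planted = []
    for k in range(n_families):
        fid = f"F{k:04d}"
        fids.append(fid)
        if k < n_universal:
            rows.append([sizes[g] for g in glabels])
            planted.append(fid)
        else:
            row = []
            for g in glabels:
                prob = (
                    presence_profile if isinstance(presence_profile, float)
                    else presence_profile.get(g, 0.5)
                )
                row.append(int(rng.binomial(sizes[g], prob)))
            rows.append(row)
    counts = pd.DataFrame(rows, index=fids, columns=glabels, dtype=int)
    return PresenceMatrix(counts, sizes), planted
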