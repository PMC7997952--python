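import dendropy
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def random_binary_tree(
    n_taxa: int, rng: np.random.Generator, mean_length: float = 0.3
) -> dendropy.Tree:
    """Random unrooted binary tree with exponential branch lengths,
    built by successive random joins."""
    subtrees = [f"t{i}" for i in range(n_taxa)]

    def bl() -> float:
        return float(rng.exponential(mean_length)) + 1e-3

    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a}:{bl():.6f},{b}:{bl():.6f})")
    nwk = "(" + ",".join(
        f"{s}:{bl():.6f}" for s in subtrees
    ) + ");"
    return make_tree(nwk)


def random_ultrametric_tree(
    n_taxa: int, rng: np.random.Generator
) -> dendropy.Tree:
    """Random strictly clocklike (ultrametric) rooted tree."""
    from ancestornet.synthetic_data import _yule_tree
    from ancestornet.tree_analysis import RootedTree

    labels = [f"t{i}" for i in range(n_taxa)]
    parent, lengths, labs = _yule_tree(labels, rng)
    return RootedTree(parent, lengths, labs).to_dendropy()


# ---------------------------------------------------------------------------
# independent oracles


def mad_grid_oracle(tree: dendropy.Tree, n_grid: int = 1000):
    """Grid-search MAD oracle working from the definition.

    For every branch and ~n_grid positions on it, places the root,
    computes each leaf pair's induced ancestor distance from the tree
    metric, evaluates the pairwise relative deviation
    |2*d(leaf, ancestor)/d(leaf, leaf') - 1|, and returns the best
    (branch split, position, rms deviation).
    """
    import networkx as nx

    g = nx.Graph()
    seed = tree.seed_node
    merge = len(seed.child_nodes()) == 2
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            if merge and nd is seed:
                continue
            g.add_edge(id(nd), id(ch), weight=float(ch.edge.length or 0.0))
    if merge:
        c1, c2 = seed.child_nodes()
        g.add_edge(
            id(c1), id(c2),
            weight=float(c1.edge.length or 0.0) + float(c2.edge.length or 0.0),
        )
    leaves = {id(nd): nd.taxon.label for nd in tree.leaf_node_iter()}
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    lids = sorted(leaves, key=lambda i: leaves[i])
    L = len(lids)
    iu = np.triu_indices(L, k=1)
    D = np.array([[dist[a][b] for b in lids] for a in lids])

    best = (np.inf, None, None)
    for u, v, data in g.edges(data=True):
        t = data["weight"]
        du = np.array([dist[a][u] for a in lids])
        dv = np.array([dist[a][v] for a in lids])
        xs = np.linspace(0.0, t, n_grid)
        droot = np.minimum(
            du[:, None] + (t - xs[None, :]), dv[:, None] + xs[None, :]
        )
        danc = (droot[iu[0]] + D[iu][:, None] - droot[iu[1]]) / 2.0
        dev = np.abs(2.0 * danc / D[iu][:, None] - 1.0)
        rms = np.sqrt((dev**2).mean(axis=0))
        k = int(rms.argmin())
        if rms[k] < best[0]:
            # leaves on the v side of the branch (paths not through u)
            side = frozenset(
                leaves[a] for a in lids if dist[a][v] < dist[a][u]
            )
            best = (float(rms[k]), side, float(xs[k]))
    return best


def f81_transition(pi: np.ndarray, t: float) -> np.ndarray:
    beta = 1.0 / (1.0 - float((pi**2).sum()))
    e = np.exp(-beta * t)
    return e * np.eye(len(pi)) + (1.0 - e) * pi[None, :]


def f81_exhaustive_root_posterior(rooted, tip_states, states, pi):
    """Sum the joint likelihood over every internal-state assignment."""
    import itertools

    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    internals = [
        i for i in range(1, rooted.n_nodes) if rooted.labels[i] is None
    ]
    post = np.zeros(k)
    for rs in range(k):
        total = 0.0
        for assign in itertools.product(range(k), repeat=len(internals)):
            state_of = {0: rs}
            state_of.update(dict(zip(internals, assign)))
            for i in range(rooted.n_nodes):
                lbl = rooted.labels[i]
                if lbl is not None:
                    state_of[i] = sidx[tip_states[lbl]]
            lik = 1.0
            for i in range(1, rooted.n_nodes):
                p = f81_transition(pi, rooted.lengths[i])
                lik *= p[state_of[rooted.parent[i]], state_of[i]]
            total += lik
        post[rs] = pi[rs] * total
    return post / post.sum()
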