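import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent random-tree machinery (oracle side; deliberately not built on
# sporekit.trees)
# ---------------------------------------------------------------------------

class TupleTree:
    """Nested-tuple tree: leaf = (name, length, None); internal =
    (None, length, [children]). Used to generate ground truth."""

    def __init__(self, name, length, children):
        self.name = name
        self.length = length
        self.children = children

    @property
    def is_leaf(self):
        return self.children is None

    def leaves(self):
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self):
        if self.is_leaf:
            return f"{self.name}:{self.length:.12g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.12g}"


def random_unrooted_tree(rng: np.random.Generator, names) -> TupleTree:
    """Random binary unrooted tree (trifurcating root) with distinct
    positive branch lengths, by random sequential joining."""
    nodes = [TupleTree(n, round(float(rng.uniform(0.05, 1.0)), 6), None) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        nodes.append(
            TupleTree(None, round(float(rng.uniform(0.05, 1.0)), 6), [b, a])
        )
    root = TupleTree(None, 0.0, nodes)
    return root


def random_rooted_tree(rng: np.random.Generator, names) -> TupleTree:
    nodes = [TupleTree(n, round(float(rng.uniform(0.05, 1.0)), 6), None) for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        nodes.append(TupleTree(None, round(float(rng.uniform(0.05, 1.0)), 6), [b, a]))
    return TupleTree(None, 0.0, nodes)


def tuple_tree_distances(tree: TupleTree) -> dict:
    """Leaf-pair path distances computed by independent recursion."""
    dists = {}

    def collect(node):
        if node.is_leaf:
            return {node.name: 0.0}
        below = []
        for child in node.children:
            d = collect(child)
            below.append({k: v + child.length for k, v in d.items()})
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        key = (a, b) if a < b else (b, a)
                        dists[key] = da + db
        merged = {}
        for d in below:
            merged.update(d)
        return merged

    collect(tree)
    return dists


def tuple_tree_splits(tree: TupleTree, all_leaves) -> set:
    """Unrooted splits (as frozenset of the smaller side, ties by sorted
    tuple) of all internal edges."""
    universe = frozenset(all_leaves)
    splits = set()

    def visit(node, is_root):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for c in node.children:
            below |= visit(c, False)
        if not is_root and 1 < len(below) < len(universe) - 1:
            other = universe - below
            splits.add(min(below, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return below

    visit(tree, True)
    return splits


def tuple_tree_clades(tree: TupleTree) -> list:
    """All rooted clades (leaf sets of internal nodes below the root)."""
    clades = []

    def visit(node, is_root):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for c in node.children:
            below |= visit(c, False)
        if not is_root:
            clades.append(below)
        return below

    visit(tree, True)
    return clades


def distance_matrix_from(names, dists) -> np.ndarray:
    n = len(names)
    d = np.zeros((n, n))
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            b = names[j]
            key = (a, b) if a < b else (b, a)
            d[i, j] = d[j, i] = dists[key]
    return d


# ---------------------------------------------------------------------------
# shared simulated dataset
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sim_params():
    from sporekit.simulate import SimulationParams

    return SimulationParams(seed=11, tracts=[("KA4", 35_000, 45_000)])


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory, sim_params):
    from sporekit.simulate import simulate

    outdir = tmp_path_factory.mktemp("sim")
    paths, truth = simulate(sim_params, outdir)
    return paths, truth
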