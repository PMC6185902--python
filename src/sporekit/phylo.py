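"""Per-window distance trees and the monophyly-based recombination scanner.

A chromosome is cut into non-overlapping windows of a fixed number of
variable sites; each window gets a BioNJ distance tree, rooted on the
outgroup, and is classified by which focal (driver) strains form a
monophyletic group. Runs of windows where fewer than all focal strains
group together mark candidate introgression/recombination tracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Interval, VariantMatrix, fixed_windows, variable_site_windows, WindowTable
from .trees import Node, PhyloTree, root_tree

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a parallel variance matrix."""

    ids: list[str]
    d: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n) or self.v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


@dataclass(frozen=True)
class MonophylyCall:
    """Per-window record of the focal clade found in that window's tree."""

    interval: Interval
    category: frozenset[str]
    support: float | None = None
    anchor_present: bool = False


@dataclass
class ScanSummary:
    """Per-bin category proportions plus the per-window support series."""

    bins: list[dict[frozenset[str], float]]
    bin_sizes: list[int]
    supports: list[float | None] = field(default_factory=list)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def p_distance(matrix: np.ndarray, ids: list[str], jukes_cantor: bool = False) -> DistanceMatrix:
    """Proportion of differing sites per sample pair.

    The variance matrix is initialized to the distance itself, the usual
    Poisson-flavoured choice for BioNJ's variance weighting. A Jukes-Cantor
    correction is available but off by default: on 50-site windows it can
    blow up near saturation.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] < 1:
        raise ValueError("window must contain at least one site")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples for tree building")
    if np.any(matrix < 0):
        raise ValueError("missing calls in window; filter variants first")
    n_sites = matrix.shape[1]
    diff = (matrix[:, None, :] != matrix[None, :, :]).sum(axis=2) / n_sites
    if jukes_cantor:
        arg = 1.0 - 4.0 * diff / 3.0
        if np.any(arg <= 0):
            raise ValueError("Jukes-Cantor undefined at saturation")
        diff = -0.75 * np.log(arg)
    np.fill_diagonal(diff, 0.0)
    return DistanceMatrix(list(ids), diff, diff.copy())


# ---------------------------------------------------------------------------
# BioNJ
# ---------------------------------------------------------------------------

def bionj(dm: DistanceMatrix) -> PhyloTree:
    """Variance-weighted neighbor joining (BioNJ).

    At each agglomeration step the pair (i, j) minimizing
    Q(i,j) = (r-2) d(i,j) - S_i - S_j is joined; branch lengths follow the
    standard NJ formulas, and reduced distances/variances use the
    variance-optimal mixing weight
    lambda = 1/2 + sum_k (v(j,k) - v(i,k)) / (2 (r-2) v(i,j)),
    clamped to [0, 1] and set to 1/2 when v(i,j) = 0 or r = 3. With equal
    variances everywhere this reduces exactly to plain neighbor joining.
    Ties in Q are broken by the smallest (i, j) index pair; negative branch
    lengths are clamped to zero (and logged). The result is unrooted, with
    a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("BioNJ needs at least 3 taxa")
    d = dm.d.copy()
    v = dm.v.copy()
    nodes: list[Node] = [Node(name) for name in dm.ids]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("clamped negative branch length %.3g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        s = sub.sum(axis=1)
        q = (r - 2) * sub - s[:, None] - s[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties broken by smallest (i, j) in the active ordering
        flat = np.argmin(q)  # row-major => lexicographically first minimum
        ai, aj = divmod(int(flat), r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = idx[ai], idx[aj]

        dij = d[i, j]
        bi = dij / 2.0 + (s[ai] - s[aj]) / (2.0 * (r - 2))
        bj = dij - bi

        vij = v[i, j]
        if vij <= 0.0:
            lam = 0.5
        else:
            others = [a for a in idx if a != i and a != j]
            lam = 0.5 + float(
                np.sum(v[j, others] - v[i, others])
            ) / (2.0 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))

        u = Node()
        ni, nj = nodes[i], nodes[j]
        # raw values feed the reduction; only stored branch lengths are clamped
        ni.length, nj.length = clamp(bi), clamp(bj)
        u.add(ni)
        u.add(nj)
        nodes[i] = u  # the merged node takes slot i

        for k in active:
            if k == i or k == j:
                continue
            duk = lam * (d[i, k] - bi) + (1.0 - lam) * (d[j, k] - bj)
            vuk = lam * v[i, k] + (1.0 - lam) * v[j, k] - lam * (1.0 - lam) * vij
            d[i, k] = d[k, i] = duk
            v[i, k] = v[k, i] = max(vuk, 0.0)
        active.remove(j)

    # final trifurcation: three remaining nodes joined at the root
    a, b, c = active
    root = Node()
    ba = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    bb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    bc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    for k, length in zip((a, b, c), (ba, bb, bc)):
        nodes[k].length = clamp(length)
        root.add(nodes[k])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# monophyly classification
# ---------------------------------------------------------------------------

def classify_grouping(
    tree: PhyloTree,
    focal: frozenset[str] | set[str],
    anchor: str | None = None,
) -> frozenset[str]:
    """Which focal strains form a monophyletic group in a rooted tree.

    Without an anchor, the category is the leaf set of the largest clade
    (of at least two leaves) whose leaves all belong to the focal set; the
    empty set is returned when no two focal strains group together. Ties on
    size are broken by the lexicographically smallest sorted id tuple.

    With an anchor (a non-focal strain of interest, e.g. the second driver
    type), the category is the focal subset of the smallest clade
    containing the anchor whose leaves lie within focal + {anchor}; empty
    when no such clade exists beyond the anchor leaf itself.
    """
    if not tree.rooted:
        raise ValueError("classify_grouping requires a rooted tree")
    focal = frozenset(focal)
    leaves = tree.leaf_names()
    if not focal <= leaves:
        raise KeyError(f"focal ids missing from tree: {sorted(focal - leaves)}")
    if anchor is not None:
        if anchor in focal:
            raise ValueError("anchor must not be a focal id")
        if anchor not in leaves:
            raise KeyError(f"anchor {anchor!r} not in tree")
        admissible = focal | {anchor}
        best: frozenset[str] | None = None
        for clade in tree.clades(min_size=2):
            if anchor in clade and clade <= admissible:
                if best is None or (
                    (len(clade), tuple(sorted(clade)))
                    < (len(best), tuple(sorted(best)))
                ):
                    best = clade
        return frozenset() if best is None else best - {anchor}

    best = None
    for clade in tree.clades(min_size=2):
        if clade <= focal:
            if best is None or (
                (-len(clade), tuple(sorted(clade)))
                < (-len(best), tuple(sorted(best)))
            ):
                best = clade
    return frozenset() if best is None else best


# ---------------------------------------------------------------------------
# windows -> calls
# ---------------------------------------------------------------------------

def _window_category(
    matrix: np.ndarray,
    ids: list[str],
    focal: frozenset[str],
    outgroup: list[str],
    anchor: str | None,
) -> frozenset[str]:
    dm = p_distance(matrix, ids)
    if np.all(dm.d == 0):
        return frozenset()  # uninformative window: no grouping claimed
    tree = root_tree(bionj(dm), outgroup)
    return classify_grouping(tree, focal, anchor)


def bootstrap_support(
    matrix: np.ndarray,
    ids: list[str],
    focal,
    outgroup: list[str],
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    anchor: str | None = None,
) -> tuple[frozenset[str], float | None]:
    """Site-resampling bootstrap support for the category observed in a window.

    Support is the fraction of replicates whose tree yields the *same*
    category as the original window (not the best category per replicate).
    Returns (category, support); support is None for an empty category.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    focal = frozenset(focal)
    category = _window_category(matrix, ids, focal, outgroup, anchor)
    if not category:
        return category, None
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_sites = matrix.shape[1]
    hits = 0
    for _ in range(reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        if _window_category(matrix[:, cols], ids, focal, outgroup, anchor) == category:
            hits += 1
    return category, hits / reps


def scan_chromosome(
    vm: VariantMatrix,
    chrom: str,
    focal,
    outgroup: list[str],
    n_sites: int = 50,
    reps: int = 100,
    bin_size: int = 50,
    anchor: str | None = None,
    seed: int = 0,
) -> tuple[list[MonophylyCall], ScanSummary]:
    """Scan one chromosome: per-window monophyly calls plus binned summary.

    Windows contain ``n_sites`` variable sites each; each window's bootstrap
    uses its own random stream derived from (seed, window index) so the scan
    is reproducible window by window. ``reps=0`` skips the bootstrap.
    The final partial bin is reported with its actual size.
    """
    focal = frozenset(focal)
    windows = variable_site_windows(vm, chrom, n_sites)
    mat = vm.alleles[chrom]
    anchor_set = frozenset([anchor]) if anchor else frozenset()
    calls: list[MonophylyCall] = []
    for w, (interval, sl) in enumerate(windows):
        sub = mat[:, sl]
        if reps > 0:
            rng = np.random.default_rng(np.random.SeedSequence([seed, w]))
            category, support = bootstrap_support(
                sub, vm.samples, focal, outgroup, reps, rng, anchor
            )
        else:
            category = _window_category(sub, vm.samples, focal, outgroup, anchor)
            support = None
        calls.append(
            MonophylyCall(interval, category, support, anchor_present=bool(anchor_set))
        )

    bins: list[dict[frozenset[str], float]] = []
    bin_sizes: list[int] = []
    for start in range(0, len(calls), bin_size):
        chunk = calls[start : start + bin_size]
        counts: dict[frozenset[str], int] = {}
        for call in chunk:
            counts[call.category] = counts.get(call.category, 0) + 1
        bins.append({cat: c / len(chunk) for cat, c in counts.items()})
        bin_sizes.append(len(chunk))
    summary = ScanSummary(bins, bin_sizes, [c.support for c in calls])
    return calls, summary


def pairwise_divergence_scan(
    vm: VariantMatrix,
    chrom: str,
    sample_a: str,
    sample_b: str,
    chrom_length: int,
    window: int = 10_000,
    step: int = 2_000,
) -> WindowTable:
    """Per-window divergence between two samples: differing variable sites
    per bp of window, over fixed sliding windows."""
    ia, ib = vm.sample_index(sample_a), vm.sample_index(sample_b)
    pos = vm.positions[chrom]
    mat = vm.alleles[chrom]
    differs = mat[ia] != mat[ib]
    cum = np.concatenate([[0], np.cumsum(differs)])
    wins = fixed_windows(chrom, chrom_length, window, step)
    values = []
    for iv in wins:
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        values.append((cum[hi] - cum[lo]) / len(iv))
    return WindowTable.from_intervals(wins).with_column("divergence", values)
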