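"""Window-level repeat landscape and chromatin statistics.

Implements the 2-kb window machinery used to relate repeat content to GC,
cytosine methylation and histone-mark (e.g. H3K9me3) enrichment: repeat
fraction per window, the >75% repeat-window classification, group
comparisons between repeat and non-repeat windows, one-sided binomial
repeat-family enrichment with Bonferroni correction, and the
region-vs-genome sliding-window confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import GenomeSequence, Interval, RepeatAnnotation, SignalTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowClassLabel:
    label: str  # "repeat" | "non_repeat"
    threshold: float


@dataclass
class EnrichmentResult:
    family: str
    region_count: float
    genome_count: float
    expected_fraction: float
    p_value: float
    significant: bool
    fold: float
    unit: str = "bp"


@dataclass
class RegionCI:
    region_value: float
    genome_mean: float
    lower: float
    upper: float
    window_size: int
    step: int
    outside: bool


# ---------------------------------------------------------------------------
# per-window statistics
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def window_repeat_fraction(
    windows: Sequence[Interval], repeats: Iterable[RepeatAnnotation]
) -> np.ndarray:
    """Fraction of each window covered by the union of repeat intervals.

    Overlapping annotations are merged first, so the fraction is invariant
    to annotation order and to splitting annotations into abutting pieces.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rep in repeats:
        iv = rep.interval
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    starts = {c: np.array([s for s, _ in m]) for c, m in merged.items()}
    ends = {c: np.array([e for _, e in m]) for c, m in merged.items()}

    out = np.zeros(len(windows))
    for i, win in enumerate(windows):
        if win.chrom not in merged:
            continue
        s, e = starts[win.chrom], ends[win.chrom]
        lo = np.clip(s, win.start, win.end)
        hi = np.clip(e, win.start, win.end)
        out[i] = np.maximum(hi - lo, 0).sum() / len(win)
    return out


def classify_repeat_windows(
    fractions: Sequence[float], threshold: float = 0.75
) -> list[WindowClassLabel]:
    """Label windows as repeat when their repeat fraction strictly exceeds
    the threshold (a fraction of exactly 0.75 is non_repeat)."""
    labels = []
    for f in fractions:
        if not 0 <= f <= 1:
            raise ValueError(f"repeat fraction {f} outside [0, 1]")
        labels.append(
            WindowClassLabel("repeat" if f > threshold else "non_repeat", threshold)
        )
    return labels


def window_gc(genome: GenomeSequence, windows: Sequence[Interval]) -> np.ndarray:
    """GC fraction per window, (G+C)/(A+C+G+T); N is ignored. NaN when a
    window contains no called bases."""
    out = np.full(len(windows), np.nan)
    for i, win in enumerate(windows):
        seq = genome.fetch(win)
        gc = seq.count("G") + seq.count("C")
        acgt = gc + seq.count("A") + seq.count("T")
        if acgt:
            out[i] = gc / acgt
    return out


def window_methylation(
    track: SignalTrack,
    windows: Sequence[Interval],
    call_threshold: float = 0.5,
    weighted: bool = False,
) -> np.ndarray:
    """Percentage of methylated cytosine sites per window.

    A covered cytosine is called methylated when methylated/total reads is
    at least ``call_threshold`` (default 0.5). Windows with no covered
    cytosines are NaN and excluded from downstream means. The alternative
    ``weighted`` mode reports 100 * sum(methylated) / sum(total) instead of
    a per-site call.
    """
    out = np.full(len(windows), np.nan)
    for i, win in enumerate(windows):
        if win.chrom not in track.positions:
            continue
        pos = track.positions[win.chrom]
        lo = np.searchsorted(pos, win.start, side="left")
        hi = np.searchsorted(pos, win.end, side="left")
        if hi == lo:
            continue
        m = track.methylated[win.chrom][lo:hi]
        t = track.total[win.chrom][lo:hi]
        covered = t > 0
        if not covered.any():
            continue
        if weighted:
            out[i] = 100.0 * m[covered].sum() / t[covered].sum()
        else:
            called = (m[covered] / t[covered]) >= call_threshold
            out[i] = 100.0 * called.mean()
    return out


def chip_fold(
    ip: SignalTrack, control: SignalTrack, windows: Sequence[Interval]
) -> np.ndarray:
    """Fold increase of immunoprecipitated coverage over the input control:
    mean IP depth / mean input depth per window; NaN where input is 0."""
    missing = set(w.chrom for w in windows) - set(ip.intervals) | (
        set(w.chrom for w in windows) - set(control.intervals)
    )
    if missing:
        raise ValueError(f"chromosomes missing from coverage tracks: {sorted(missing)}")
    out = np.full(len(windows), np.nan)
    for i, win in enumerate(windows):
        denom = control.mean_depth(win)
        if denom > 0:
            out[i] = ip.mean_depth(win) / denom
    return out


# ---------------------------------------------------------------------------
# group comparison (repeat vs non-repeat windows)
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    t: float
    p: float
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    degenerate: bool = False


def compare_groups(values_a, values_b, welch: bool = False) -> GroupComparison:
    """Two-sample t test between window groups (pooled-variance Student's t
    by default, Welch via flag), with per-group mean +/- 1.96 SE intervals
    for plotting."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")

    def ci(x):
        se = x.std(ddof=1) / math.sqrt(x.size)
        return (x.mean() - 1.96 * se, x.mean() + 1.96 * se)

    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, 1.0, a.mean(), b.mean(), ci(a), ci(b))
        return GroupComparison(
            math.inf if a.mean() > b.mean() else -math.inf,
            0.0, a.mean(), b.mean(), ci(a), ci(b), degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(float(t), float(p), a.mean(), b.mean(), ci(a), ci(b))


# ---------------------------------------------------------------------------
# repeat-family enrichment
# ---------------------------------------------------------------------------

def family_enrichment(
    region_repeats: Iterable[RepeatAnnotation],
    genome_repeats: Iterable[RepeatAnnotation],
    region_len: int,
    genome_len: int,
    alpha: float = 0.05,
    unit: str = "bp",
) -> list[EnrichmentResult]:
    """One-sided binomial enrichment of each repeat family in a region.

    For each family, k = family content in the region, n = region length
    (or region annotation count), p0 = genome-wide family fraction; the
    p-value is the upper binomial tail P(X >= k | n, p0). Significance is
    Bonferroni-corrected across the families tested. ``unit`` selects base
    pairs (default; matches regional percentage-of-sequence bookkeeping) or
    per-annotation counts.
    """
    if unit not in ("bp", "count"):
        raise ValueError("unit must be 'bp' or 'count'")

    def tally(reps):
        counts: dict[str, float] = {}
        for rep in reps:
            amount = len(rep.interval) if unit == "bp" else 1
            counts[rep.family] = counts.get(rep.family, 0) + amount
        return counts

    region_repeats = list(region_repeats)
    region = tally(region_repeats)
    genome = tally(genome_repeats)
    if unit == "count":
        region_len = max(len(region_repeats), 1)
        genome_len = max(int(sum(genome.values())), 1)

    families = sorted(set(region) | set(genome))
    tested = [f for f in families if genome.get(f, 0) > 0]
    for f in families:
        if f not in tested:
            log.warning("family %s absent genome-wide; skipped", f)
    m = max(len(tested), 1)
    results = []
    for fam in tested:
        k = int(region.get(fam, 0))
        p0 = genome[fam] / genome_len
        p_value = float(stats.binom.sf(k - 1, region_len, p0))  # P(X >= k)
        fold = (k / region_len) / p0
        results.append(
            EnrichmentResult(
                family=fam,
                region_count=k,
                genome_count=genome[fam],
                expected_fraction=p0,
                p_value=p_value,
                significant=p_value < alpha / m,
                fold=fold,
                unit=unit,
            )
        )
    return results


# ---------------------------------------------------------------------------
# region vs genome sliding-window CI
# ---------------------------------------------------------------------------

def region_vs_genome_ci(
    window_values,
    region_value: float,
    window_size: int = 0,
    step: int = 200_000,
) -> RegionCI:
    """Compare a region-level statistic against genome sliding windows of
    the same size: the genome mean with empirical 2.5/97.5 percentile
    bounds (linear interpolation), flagging whether the region lies outside.
    """
    values = np.asarray(window_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise ValueError(
            "need >= 20 genome windows for a stable interval; use a smaller step"
        )
    lower, upper = np.percentile(values, [2.5, 97.5])
    mean = float(values.mean())
    return RegionCI(
        region_value=float(region_value),
        genome_mean=mean,
        lower=float(lower),
        upper=float(upper),
        window_size=window_size,
        step=step,
        outside=not (lower <= region_value <= upper),
    )
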