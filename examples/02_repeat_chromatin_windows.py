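"""Repeat windows and chromatin marks: 2-kb window statistics, the >75%
repeat-window classification, repeat vs non-repeat group comparison and
repeat-family enrichment in the drive region.
"""

import numpy as np

import sporekit as sk
from sporekit.simulate import SimulationParams, simulate

paths, truth = simulate(SimulationParams(seed=42), "scratch/example02")
genome = sk.read_fasta(paths["fasta"])
repeats = sk.read_repeatmasker(paths["repeats"])
meth = sk.read_methylation(paths["methylation"], genome.lengths)
ip = sk.read_coverage(paths["ip"], genome.lengths)
ctl = sk.read_coverage(paths["input"], genome.lengths)

windows = []
for chrom, length in genome.lengths.items():
    windows.extend(sk.fixed_windows(chrom, length, 2_000, 2_000))

frac = sk.window_repeat_fraction(windows, repeats)
labels = [l.label for l in sk.classify_repeat_windows(frac)]
gc = sk.window_gc(genome, windows)
meth_pct = sk.window_methylation(meth, windows)
fold = sk.chip_fold(ip, ctl, windows)

is_rep = np.array([l == "repeat" for l in labels])
print(f"{is_rep.sum()} repeat windows, {(~is_rep).sum()} non-repeat windows")
for name, col in [("GC", gc), ("methylation %", meth_pct), ("IP fold", fold)]:
    cmp = sk.compare_groups(col[is_rep], col[~is_rep])
    print(
        f"{name:14s} repeat {cmp.mean_a:7.3f} vs non-repeat {cmp.mean_b:7.3f} "
        f"(t={cmp.t:8.1f}, p={cmp.p:.3g})"
    )

chrom, start, end = truth.region
region_iv = sk.Interval(chrom, start, end)
region_reps = [r for r in repeats if r.interval.overlaps(region_iv)]
print("\nfamily enrichment in the drive region (one-sided binomial, Bonferroni):")
for res in sk.family_enrichment(
    region_reps, repeats, end - start, sum(genome.lengths.values())
):
    flag = "*" if res.significant else " "
    print(f" {flag} {res.family:12s} fold={res.fold:5.2f}  p={res.p_value:.3g}")
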