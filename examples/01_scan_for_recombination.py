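"""Sliding-window monophyly scan: find where a driver haplotype has
recombined with the sensitive background.

Simulates a non-recombining region for four driver strains with one planted
introgression tract, builds a BioNJ tree for every 50-variable-site window,
roots it on the outgroup and reports which driver strains form a clade.
"""

from sporekit import scan_chromosome
from sporekit.simulate import SimulationParams, simulate_scan_matrix

params = SimulationParams(seed=42, tracts=[("KA3", 34_000, 46_000)])
vm = simulate_scan_matrix(params)

calls, summary = scan_chromosome(
    vm, "chr3", focal=params.killers_a, outgroup=params.outgroups,
    n_sites=50, reps=0, bin_size=50,
)

print(f"windows scanned: {len(calls)}")
for b, props in enumerate(summary.bins):
    desc = ", ".join(
        f"{{{'+'.join(sorted(cat)) or 'none'}}}: {frac:.0%}"
        for cat, frac in sorted(props.items(), key=lambda kv: -kv[1])
    )
    print(f"bin {b}: {desc}")

three = frozenset(params.killers_a) - {"KA3"}
tract_windows = [c for c in calls if c.category == three]
print(
    f"\nKA3 drops out of the driver clade in {len(tract_windows)} windows "
    f"spanning {tract_windows[0].interval.start}-{tract_windows[-1].interval.end} bp"
)
print("(the planted tract was 34000-46000 bp: a recombination event with the")
print(" sensitive background is localized to within one window)")
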