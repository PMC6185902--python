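"""Core data model: genome sequences, intervals, SNP matrices, gene models,
signal tracks, window tables, plus the two windowing schemes and the variant
filter that every downstream analysis consumes.

Coordinates are 0-based half-open everywhere inside the package; conversion
from the 1-based conventions of VCF, GFF3 and RepeatMasker happens once, at
the file boundary (see :mod:`sporekit.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: allele encoding used throughout: A=0, C=1, G=2, T=3, missing=-1
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASE = "ACGT"
MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide strings over the alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("duplicate chromosome identifiers")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, iv: Interval) -> str:
        seq = self.sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"{iv} exceeds chromosome length {len(seq)}")
        return seq[iv.start : iv.end]


@dataclass
class VariantMatrix:
    """Haploid SNP genotypes: ordered samples x ascending positions.

    ``positions`` maps chromosome -> strictly increasing 0-based positions;
    ``alleles`` maps chromosome -> int8 array of shape
    (n_samples, n_sites) with codes 0..3 for A,C,G,T and -1 for missing.
    ``ref``/``alt`` hold the per-site reference and alternate base codes.
    """

    samples: list[str]
    positions: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]
    ref: dict[str, np.ndarray] = field(default_factory=dict)
    alt: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.samples)
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = pos
            mat = np.asarray(self.alleles[chrom], dtype=np.int8)
            self.alleles[chrom] = mat
            if mat.shape != (n, pos.size):
                raise ValueError(
                    f"{chrom}: allele matrix {mat.shape} != "
                    f"({n}, {pos.size})"
                )
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: positions not strictly ascending")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def n_sites(self, chrom: str) -> int:
        return self.positions[chrom].size

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def take_sites(self, chrom: str, mask_or_index) -> "VariantMatrix":
        """New matrix restricted to the selected sites of one chromosome."""
        pos = self.positions[chrom][mask_or_index]
        mat = self.alleles[chrom][:, mask_or_index]
        ref = {chrom: self.ref[chrom][mask_or_index]} if chrom in self.ref else {}
        alt = {chrom: self.alt[chrom][mask_or_index]} if chrom in self.alt else {}
        return VariantMatrix(
            samples=list(self.samples),
            positions={chrom: pos},
            alleles={chrom: mat},
            ref=ref,
            alt=alt,
        )


@dataclass
class GeneModel:
    """Protein-coding gene with ordered CDS intervals.

    CDS intervals are stored in 5'->3' transcription order (i.e. reversed
    genomic order on the minus strand); ``valid`` is False when the spliced
    length is not a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        ordered = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        self.cds = ordered if self.strand == "+" else ordered[::-1]

    @property
    def spliced_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    @property
    def valid(self) -> bool:
        return self.spliced_length % 3 == 0

    @property
    def span(self) -> Interval:
        return Interval(
            self.chrom,
            min(iv.start for iv in self.cds),
            max(iv.end for iv in self.cds),
            self.strand,
        )

    @property
    def midpoint(self) -> int:
        s = self.span
        return (s.start + s.end) // 2


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: Interval
    family: str
    repeat_class: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")


@dataclass
class SignalTrack:
    """Sparse per-position signal.

    Methylation dialect: ``positions`` -> per-cytosine (methylated, total)
    read counts. Coverage dialect: run-length intervals with a depth value.
    Exactly one of the two representations is populated per track.
    """

    # methylation representation
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    methylated: dict[str, np.ndarray] = field(default_factory=dict)
    total: dict[str, np.ndarray] = field(default_factory=dict)
    # coverage representation: (starts, ends, values) per chromosome
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for chrom in self.positions:
            m = np.asarray(self.methylated[chrom], dtype=float)
            t = np.asarray(self.total[chrom], dtype=float)
            if np.any(m < 0) or np.any(t < 0) or np.any(m > t):
                raise ValueError(f"{chrom}: need 0 <= methylated <= total")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions or self.intervals)

    def mean_depth(self, iv: Interval) -> float:
        """Mean per-bp depth of a coverage track over ``iv`` (0 outside data)."""
        starts, ends, values = self.intervals[iv.chrom]
        lo = np.clip(starts, iv.start, iv.end)
        hi = np.clip(ends, iv.start, iv.end)
        covered = np.maximum(hi - lo, 0)
        return float(np.sum(covered * values) / len(iv))


@dataclass
class WindowTable:
    """Ordered windows plus named per-window columns (a thin pandas wrapper)."""

    frame: pd.DataFrame  # columns: chrom, start, end, plus data columns

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"window table needs columns {sorted(required)}")
        f = self.frame.sort_values(["chrom", "start"], kind="stable")
        self.frame = f.reset_index(drop=True)

    @classmethod
    def from_intervals(cls, windows: Sequence[Interval]) -> "WindowTable":
        return cls(
            pd.DataFrame(
                {
                    "chrom": [w.chrom for w in windows],
                    "start": [w.start for w in windows],
                    "end": [w.end for w in windows],
                }
            )
        )

    def intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end))
            for r in self.frame.itertuples()
        ]

    def with_column(self, name: str, values) -> "WindowTable":
        f = self.frame.copy()
        f[name] = values
        return WindowTable(f)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# windowing schemes
# ---------------------------------------------------------------------------

def repeat_tree(repeats: Iterable[RepeatAnnotation]) -> dict[str, IntervalTree]:
    """Interval trees per chromosome for O(log n) point/overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        iv = rep.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rep)
    return trees


def filter_variants(
    vm: VariantMatrix, repeats: Iterable[RepeatAnnotation]
) -> VariantMatrix:
    """Drop sites inside any repeat interval and sites with any missing call.

    Mirrors the SNP-set cleanup used upstream of every window analysis:
    repeat-annotated sites are unreliable to align and genotype, and a site
    missing in any haploid sample would make pairwise distances unequal in
    information content. Sample order is preserved; the result may be empty.
    """
    trees = repeat_tree(repeats)
    positions: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    ref: dict[str, np.ndarray] = {}
    alt: dict[str, np.ndarray] = {}
    for chrom in vm.chromosomes:
        pos = vm.positions[chrom]
        mat = vm.alleles[chrom]
        keep = ~np.any(mat == MISSING, axis=0)
        tree = trees.get(chrom)
        if tree is not None:
            in_repeat = np.fromiter(
                (bool(tree[int(p)]) for p in pos), dtype=bool, count=pos.size
            )
            keep &= ~in_repeat
        n_drop = int(pos.size - keep.sum())
        if n_drop:
            log.info("%s: filtered %d of %d sites", chrom, n_drop, pos.size)
        positions[chrom] = pos[keep]
        alleles[chrom] = mat[:, keep]
        if chrom in vm.ref:
            ref[chrom] = vm.ref[chrom][keep]
        if chrom in vm.alt:
            alt[chrom] = vm.alt[chrom][keep]
        if keep.sum() == 0:
            log.warning("%s: no sites retained after filtering", chrom)
    return VariantMatrix(list(vm.samples), positions, alleles, ref, alt)


def variable_site_windows(
    vm: VariantMatrix, chrom: str, n_sites: int = 50
) -> list[tuple[Interval, slice]]:
    """Consecutive non-overlapping blocks of exactly ``n_sites`` variable sites.

    The trailing partial block is dropped (and logged): windows of unequal
    site counts would carry unequal phylogenetic information. Each interval
    spans the first to last site position of its block.
    """
    if n_sites < 2 and n_sites != 1:
        raise ValueError("n_sites must be >= 1")
    if chrom not in vm.positions:
        raise KeyError(f"chromosome {chrom!r} not in matrix")
    pos = vm.positions[chrom]
    n_windows = pos.size // n_sites
    dropped = pos.size - n_windows * n_sites
    if dropped:
        log.info("%s: dropped trailing partial window of %d sites", chrom, dropped)
    out = []
    for w in range(n_windows):
        sl = slice(w * n_sites, (w + 1) * n_sites)
        out.append(
            (Interval(chrom, int(pos[sl.start]), int(pos[sl.stop - 1]) + 1), sl)
        )
    return out


def fixed_windows(
    chrom: str, chrom_length: int, size: int, step: int
) -> list[Interval]:
    """Fixed-width sliding windows starting at 0, step, 2*step, ...

    Only windows that fit entirely on the chromosome are emitted, so with
    step == size the scheme tiles the chromosome prefix without overlap.
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    return [
        Interval(chrom, start, start + size)
        for start in range(0, chrom_length - size + 1, step)
    ]
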