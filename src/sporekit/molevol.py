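"""Coding-sequence diversity and divergence.

Nei–Gojobori (1986) site and difference counting underpins everything:
per-gene πN/πS within the ingroup, fixed-difference divergence counts to an
outgroup, pooled McDonald–Kreitman tables with the neutrality index
NI = (PN/PS)/(DN/DS), a gene-resampling bootstrap null with length
rescaling for count statistics, and a lower bound on the age of a
non-recombining haplotype from minimum pairwise synonymous divergence.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .core import CODE_BASE, MISSING, GeneModel, GenomeSequence, VariantMatrix

log = logging.getLogger(__name__)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"
SENSE_CODONS = tuple(sorted(_CODON_TABLE))


def translate(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return _CODON_TABLE.get(codon)


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon) and codon not in _STOPS


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts (N, S) of a sense codon.

    Each position contributes the fraction of its single-nucleotide mutants
    that are synonymous; mutants that create a stop codon are excluded from
    both numerator and denominator, so N + S = 3 for every sense codon.
    """
    if codon in _STOPS or codon not in _CODON_TABLE:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = _CODON_TABLE[codon]
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            valid += 1
            if _CODON_TABLE[mut] == aa:
                syn += 1
        if valid:
            s_sites += syn / valid
    return 3.0 - s_sites, s_sites


@lru_cache(maxsize=None)
def pairwise_codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (nonsynonymous, synonymous) change counts between two sense
    codons over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked (possible only for some triple differences) all pathways are
    used as a fallback. The two counts always sum to the Hamming distance.
    """
    for c in (codon_a, codon_b):
        if not is_valid_codon(c):
            raise ValueError(f"{c!r} is not a sense codon")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        n = s = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                return None
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        return float(n), float(s)

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:  # fallback: count through stops rather than drop the codon
        valid = []
        for order in itertools.permutations(diff_pos):
            cur = codon_a
            n = s = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                same = cur not in _STOPS and nxt not in _STOPS and _CODON_TABLE.get(
                    cur
                ) == _CODON_TABLE.get(nxt)
                s += same
                n += not same
                cur = nxt
            valid.append((float(n), float(s)))
    n = sum(p[0] for p in valid) / len(valid)
    s = sum(p[1] for p in valid) / len(valid)
    return n, s


# ---------------------------------------------------------------------------
# alignments and per-gene statistics
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Spliced CDS haplotypes for one gene (ingroup, optional outgroup)."""

    gene_id: str
    ingroup: dict[str, str]
    outgroup: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.ingroup.values()} | {
            len(s) for s in self.outgroup.values()
        }
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        (self.length,) = lengths
        if self.length % 3:
            raise ValueError(f"{self.gene_id}: length {self.length} not multiple of 3")

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, seq: str, i: int) -> str:
        return seq[3 * i : 3 * i + 3]

    def has_internal_stop(self) -> bool:
        for seq in {**self.ingroup, **self.outgroup}.values():
            for i in range(self.n_codons - 1):
                if self.codon(seq, i) in _STOPS:
                    return True
        return False


@dataclass
class GeneStats:
    """Per-gene diversity and MK counts, keeping per-pair sums so that
    pooling across genes is exactly equivalent to concatenating alignments."""

    gene_id: str
    length: int
    pair_keys: list[tuple[str, str]]
    pair_n_diffs: np.ndarray
    pair_s_diffs: np.ndarray
    pair_n_sites: np.ndarray
    pair_s_sites: np.ndarray
    pair_total_diffs: np.ndarray
    p_n: float
    p_s: float
    d_n: float
    d_s: float

    @property
    def pi_n(self) -> float:
        return float(np.mean(self.pair_n_diffs / self.pair_n_sites))

    @property
    def pi_s(self) -> float:
        return float(np.mean(self.pair_s_diffs / self.pair_s_sites))

    @property
    def pi_total(self) -> float:
        return float(np.mean(self.pair_total_diffs) / self.length)


@dataclass
class DiversityStats:
    pi_total: float
    pi_n: float
    pi_s: float
    n_sites: float
    s_sites: float

    @property
    def pi_n_over_pi_s(self) -> float | None:
        return self.pi_n / self.pi_s if self.pi_s > 0 else None


@dataclass
class MKTable:
    """Pooled McDonald–Kreitman counts."""

    p_n: float
    p_s: float
    d_n: float
    d_s: float

    def __post_init__(self) -> None:
        if min(self.p_n, self.p_s, self.d_n, self.d_s) < 0:
            raise ValueError("MK counts must be non-negative")

    @property
    def pn_ps(self) -> float | None:
        return self.p_n / self.p_s if self.p_s > 0 else None

    @property
    def dn_ds(self) -> float | None:
        return self.d_n / self.d_s if self.d_s > 0 else None


def neutrality_index(mk: MKTable) -> float:
    """NI = (PN/PS)/(DN/DS); >1 suggests segregating deleterious variation
    (relaxed/negative selection), <1 an excess of fixed nonsynonymous
    changes (positive selection)."""
    if mk.p_s <= 0 or mk.d_n <= 0 or mk.d_s <= 0:
        raise ValueError("NI undefined: needs PS > 0, DN > 0 and DS > 0")
    return (mk.p_n / mk.p_s) / (mk.d_n / mk.d_s)


def _usable(codon: str) -> bool:
    return is_valid_codon(codon)


def gene_diversity_pairs(aln: CodonAlignment):
    """Yield per-pair (n_diffs, s_diffs, N_sites, S_sites, total_diffs).

    For each ingroup pair, codons carrying ambiguity or a stop in either
    member are excluded for that pair; site counts are the mean of the two
    codons' NG86 counts, summed over usable codons.
    """
    ids = sorted(aln.ingroup)
    for a, b in itertools.combinations(ids, 2):
        sa, sb = aln.ingroup[a], aln.ingroup[b]
        n_d = s_d = n_sites = s_sites = total = 0.0
        for i in range(aln.n_codons):
            ca, cb = aln.codon(sa, i), aln.codon(sb, i)
            if not (_usable(ca) and _usable(cb)):
                continue
            na, ssa = ng86_site_counts(ca)
            nb, ssb = ng86_site_counts(cb)
            n_sites += (na + nb) / 2.0
            s_sites += (ssa + ssb) / 2.0
            if ca != cb:
                dn, ds = pairwise_codon_diffs(ca, cb)
                n_d += dn
                s_d += ds
                total += sum(x != y for x, y in zip(ca, cb))
        yield (a, b), n_d, s_d, n_sites, s_sites, total


def polymorphism_counts(aln: CodonAlignment) -> tuple[float, float]:
    """Segregating nonsynonymous/synonymous change counts (PN, PS) within
    the ingroup: each segregating codon's changes are counted against the
    majority (consensus) codon of that column."""
    p_n = p_s = 0.0
    ids = sorted(aln.ingroup)
    for i in range(aln.n_codons):
        codons = [aln.codon(aln.ingroup[s], i) for s in ids]
        codons = [c for c in codons if _usable(c)]
        distinct = sorted(set(codons))
        if len(distinct) < 2:
            continue
        consensus = max(distinct, key=lambda c: (codons.count(c), c))
        for other in distinct:
            if other == consensus:
                continue
            dn, ds = pairwise_codon_diffs(consensus, other)
            p_n += dn
            p_s += ds
    return p_n, p_s


def gene_divergence(aln: CodonAlignment) -> tuple[float, float]:
    """Fixed-difference divergence counts (DN, DS) to the outgroup.

    A codon position contributes only when all ingroup sequences share one
    sense codon, all outgroup sequences share another, and they differ;
    positions polymorphic in either group contribute to P, not D.
    """
    if not aln.outgroup:
        raise ValueError(f"{aln.gene_id}: no outgroup sequences")
    d_n = d_s = 0.0
    for i in range(aln.n_codons):
        in_codons = {aln.codon(s, i) for s in aln.ingroup.values()}
        out_codons = {aln.codon(s, i) for s in aln.outgroup.values()}
        if len(in_codons) != 1 or len(out_codons) != 1:
            continue
        (ci,), (co) = in_codons, out_codons.pop()
        if not (_usable(ci) and _usable(co)) or ci == co:
            continue
        dn, ds = pairwise_codon_diffs(ci, co)
        d_n += dn
        d_s += ds
    return d_n, d_s


def gene_stats(aln: CodonAlignment) -> GeneStats:
    """All per-gene statistics in one pass; raises on invalid genes
    (internal stops, <2 ingroup sequences)."""
    if len(aln.ingroup) < 2:
        raise ValueError(f"{aln.gene_id}: need >= 2 ingroup sequences")
    if aln.has_internal_stop():
        raise ValueError(f"{aln.gene_id}: internal stop codon")
    keys, nd, sd, ns, ss, tot = [], [], [], [], [], []
    for key, n_d, s_d, n_sites, s_sites, total in gene_diversity_pairs(aln):
        keys.append(key)
        nd.append(n_d)
        sd.append(s_d)
        ns.append(n_sites)
        ss.append(s_sites)
        tot.append(total)
    p_n, p_s = polymorphism_counts(aln)
    if aln.outgroup:
        d_n, d_s = gene_divergence(aln)
    else:
        d_n = d_s = 0.0
    return GeneStats(
        gene_id=aln.gene_id,
        length=aln.length,
        pair_keys=keys,
        pair_n_diffs=np.array(nd),
        pair_s_diffs=np.array(sd),
        pair_n_sites=np.array(ns),
        pair_s_sites=np.array(ss),
        pair_total_diffs=np.array(tot),
        p_n=p_n,
        p_s=p_s,
        d_n=d_n,
        d_s=d_s,
    )


def gene_diversity(aln: CodonAlignment) -> DiversityStats:
    """Per-gene πN, πS and π_total (mean over ingroup pairs)."""
    gs = gene_stats(aln)
    return DiversityStats(
        pi_total=gs.pi_total,
        pi_n=gs.pi_n,
        pi_s=gs.pi_s,
        n_sites=float(np.mean(gs.pair_n_sites)),
        s_sites=float(np.mean(gs.pair_s_sites)),
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(genes: Sequence[GeneStats]) -> tuple[DiversityStats, MKTable]:
    """Pool genes as if their alignments were concatenated.

    P/D counts are summed; π values are length-weighted: per-pair diff and
    site sums are added across genes and the ratio is averaged over pairs,
    which equals recomputation on the concatenated alignment when all genes
    share the same ingroup.
    """
    if not genes:
        raise ValueError("no genes to aggregate")
    keys = genes[0].pair_keys
    for g in genes[1:]:
        if g.pair_keys != keys:
            raise ValueError("genes have differing ingroup pair sets")
    nd = sum(g.pair_n_diffs for g in genes)
    sd = sum(g.pair_s_diffs for g in genes)
    ns = sum(g.pair_n_sites for g in genes)
    ss = sum(g.pair_s_sites for g in genes)
    tot = sum(g.pair_total_diffs for g in genes)
    length = sum(g.length for g in genes)
    diversity = DiversityStats(
        pi_total=float(np.mean(tot) / length),
        pi_n=float(np.mean(nd / ns)),
        pi_s=float(np.mean(sd / ss)),
        n_sites=float(np.mean(ns)),
        s_sites=float(np.mean(ss)),
    )
    mk = MKTable(
        p_n=sum(g.p_n for g in genes),
        p_s=sum(g.p_s for g in genes),
        d_n=sum(g.d_n for g in genes),
        d_s=sum(g.d_s for g in genes),
    )
    return diversity, mk


def assign_partition(
    gene: GeneModel, region: "tuple[str, int, int] | None"
) -> str:
    """Partition key for a gene: the drive region (by CDS midpoint, logged
    for straddlers) or its chromosome."""
    if region is not None:
        chrom, start, end = region
        if gene.chrom == chrom:
            span = gene.span
            if span.start < end and span.end > start and not (
                start <= span.start and span.end <= end
            ):
                log.info("%s straddles region boundary; assigned by midpoint", gene.gene_id)
            if start <= gene.midpoint < end:
                return "region"
    return gene.chrom


# ---------------------------------------------------------------------------
# gene-resampling bootstrap null
# ---------------------------------------------------------------------------

@dataclass
class BootstrapNull:
    statistic: str
    replicates: np.ndarray
    observed: float | None
    lower: float
    upper: float
    p_value: float | None
    reps: int
    seed: int


_COUNT_STATS = ("p_n", "p_s", "d_n", "d_s")
_RATIO_STATS = ("pi_n", "pi_s", "pi_n_over_pi_s", "pn_ps", "dn_ds", "ni")


def _pooled_stats(genes: Sequence[GeneStats], scale: float) -> dict[str, float]:
    nd = float(sum(g.pair_n_diffs.sum() for g in genes))
    sd = float(sum(g.pair_s_diffs.sum() for g in genes))
    ns = float(sum(g.pair_n_sites.sum() for g in genes))
    ss = float(sum(g.pair_s_sites.sum() for g in genes))
    p_n = sum(g.p_n for g in genes)
    p_s = sum(g.p_s for g in genes)
    d_n = sum(g.d_n for g in genes)
    d_s = sum(g.d_s for g in genes)
    out = {
        "p_n": p_n * scale,
        "p_s": p_s * scale,
        "d_n": d_n * scale,
        "d_s": d_s * scale,
        "pi_n": nd / ns if ns else math.nan,
        "pi_s": sd / ss if ss else math.nan,
    }
    out["pi_n_over_pi_s"] = out["pi_n"] / out["pi_s"] if out["pi_s"] else math.nan
    out["pn_ps"] = p_n / p_s if p_s else math.nan
    out["dn_ds"] = d_n / d_s if d_s else math.nan
    out["ni"] = (
        (p_n / p_s) / (d_n / d_s) if p_s > 0 and d_s > 0 and d_n > 0 else math.nan
    )
    return out


def bootstrap_null(
    background_genes: Sequence[GeneStats],
    n_region_genes: int,
    region_length: float,
    reps: int = 1000,
    seed: int = 0,
    observed: Mapping[str, float] | None = None,
) -> dict[str, BootstrapNull]:
    """Gene-resampling null distribution for every pooled statistic.

    Each replicate draws ``n_region_genes`` background genes with
    replacement and pools them. Count statistics (PN, PS, DN, DS) are
    rescaled by region_length / total sampled gene length so they are
    comparable with the region's totals; ratio statistics are unscaled.
    The empirical two-sided p-value is 2*min(r, 1-r) with
    r = (1 + #{replicates <= observed}) / (reps + 1).
    """
    if reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    if not background_genes:
        raise ValueError("empty background gene set")
    rng = np.random.default_rng(seed)
    names = _COUNT_STATS + tuple(s for s in _RATIO_STATS)
    draws: dict[str, list[float]] = {n: [] for n in names}
    genes = list(background_genes)
    for _ in range(reps):
        picked = [genes[i] for i in rng.integers(0, len(genes), size=n_region_genes)]
        total_len = sum(g.length for g in picked)
        stats = _pooled_stats(picked, scale=region_length / total_len)
        for n in names:
            draws[n].append(stats[n])
    out: dict[str, BootstrapNull] = {}
    for n in names:
        rep = np.array(draws[n])
        finite = rep[np.isfinite(rep)]
        lower, upper = np.percentile(finite, [2.5, 97.5])
        p = None
        obs = None if observed is None else observed.get(n)
        if obs is not None and finite.size:
            r = (1 + int(np.sum(finite <= obs))) / (finite.size + 1)
            p = 2 * min(r, 1 - r)
        out[n] = BootstrapNull(n, rep, obs, float(lower), float(upper), p, reps, seed)
    return out


# ---------------------------------------------------------------------------
# age lower bound from minimum synonymous divergence
# ---------------------------------------------------------------------------

@dataclass
class AgeEstimate:
    per_gene_ds: dict[str, float]
    per_gene_partner: dict[str, str]
    pooled_ds: float
    subs_rate_per_year: float
    age_years: float


def pairwise_ds(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(synonymous diffs, synonymous sites) between two equal-length CDS."""
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise ValueError("sequences must be equal-length codon alignments")
    s_d = s_sites = 0.0
    for i in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3]
        if not (_usable(ca) and _usable(cb)):
            continue
        _, ssa = ng86_site_counts(ca)
        _, ssb = ng86_site_counts(cb)
        s_sites += (ssa + ssb) / 2.0
        if ca != cb:
            _, ds = pairwise_codon_diffs(ca, cb)
            s_d += ds
    return s_d, s_sites


def age_lower_bound(
    region_genes: Mapping[str, str],
    sensitive_panel: Mapping[str, Mapping[str, str]],
    subs_rate_per_year: float,
) -> AgeEstimate:
    """Lower bound on the age of a non-recombining haplotype.

    For each gene, the synonymous divergence between the region haplotype
    and *every* member of a freely recombining sensitive panel is computed
    and the minimizing partner kept — because the panel recombines, no
    single strain is uniformly closest, and taking the per-gene minimum
    makes the pooled estimate a lower bound. The pooled dS is
    sum(s_diffs)/sum(S_sites) over genes (each with its minimizing
    partner) and age = dS / (2 * rate).
    """
    if subs_rate_per_year <= 0:
        raise ValueError("substitution rate must be > 0")
    per_gene: dict[str, float] = {}
    partners: dict[str, str] = {}
    sum_sd = sum_sites = 0.0
    for gene_id, region_seq in region_genes.items():
        panel = sensitive_panel.get(gene_id, {})
        if not panel:
            raise KeyError(f"{gene_id}: no sensitive-panel orthologs")
        best = None
        for name in sorted(panel):
            s_d, s_sites = pairwise_ds(region_seq, panel[name])
            if s_sites <= 0:
                continue
            ds = s_d / s_sites
            if best is None or ds < best[0]:
                best = (ds, name, s_d, s_sites)
        if best is None:
            log.info("%s: zero synonymous sites; excluded from age bound", gene_id)
            continue
        per_gene[gene_id] = best[0]
        partners[gene_id] = best[1]
        sum_sd += best[2]
        sum_sites += best[3]
    if sum_sites == 0:
        raise ValueError("no genes usable for the age bound")
    pooled = sum_sd / sum_sites
    return AgeEstimate(
        per_gene_ds=per_gene,
        per_gene_partner=partners,
        pooled_ds=pooled,
        subs_rate_per_year=subs_rate_per_year,
        age_years=pooled / (2.0 * subs_rate_per_year),
    )


# ---------------------------------------------------------------------------
# CDS haplotype reconstruction from genome + gene model + SNP matrix
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def build_codon_alignment(
    gene: GeneModel,
    genome: GenomeSequence,
    vm: VariantMatrix,
    ingroup: Sequence[str],
    outgroup: Sequence[str] = (),
) -> CodonAlignment:
    """Reconstruct spliced CDS haplotypes by substituting each sample's
    alleles into the reference CDS (reverse-complemented on minus strand).
    Missing calls become N and are excluded codon-wise downstream."""
    if not gene.valid:
        raise ValueError(f"{gene.gene_id}: spliced length not a multiple of 3")
    # genomic positions of the spliced CDS, 5'->3'
    genome_pos: list[int] = []
    for iv in gene.cds:
        rng = range(iv.start, iv.end)
        genome_pos.extend(reversed(rng) if gene.strand == "-" else rng)
    ref_chrom = genome.sequences[gene.chrom]
    ref_bases = [ref_chrom[p] for p in genome_pos]
    if gene.strand == "-":
        ref_bases = [_COMPLEMENT[b] for b in ref_bases]
    pos_index = {p: i for i, p in enumerate(genome_pos)}

    chrom_pos = vm.positions.get(gene.chrom, np.empty(0, dtype=np.int64))
    hits = [
        (j, pos_index[int(p)]) for j, p in enumerate(chrom_pos) if int(p) in pos_index
    ]

    def haplotype(sample: str) -> str:
        si = vm.sample_index(sample)
        seq = list(ref_bases)
        for j, k in hits:
            code = int(vm.alleles[gene.chrom][si, j])
            if code == MISSING:
                seq[k] = "N"
                continue
            base = CODE_BASE[code]
            seq[k] = _COMPLEMENT[base] if gene.strand == "-" else base
        return "".join(seq)

    return CodonAlignment(
        gene_id=gene.gene_id,
        ingroup={s: haplotype(s) for s in ingroup},
        outgroup={s: haplotype(s) for s in outgroup},
    )
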