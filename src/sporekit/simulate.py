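"""Seeded generator of a complete toy dataset with the statistical structure
the analyses assume, plus a machine-readable truth record.

The simulated species is a multi-strain haploid fungus: a freely
recombining "sensitive" background, a set of driver ("killer") strains
whose non-recombining region sits on one chromosome and descends from a
deep two-clade genealogy, an outgroup species, planted introgression
tracts, low-GC repeat clusters carrying high cytosine methylation and
elevated IP coverage, and protein-coding genes whose synonymous and
nonsynonymous variation is planted with exact NG86 classification.

No coalescent machinery is used: genealogies are fixed and mutation counts
are Poisson, which keeps every expectation analytic and every pipeline
stage scorable against the truth record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import CODE_BASE, BASE_CODE, GenomeSequence, Interval, VariantMatrix
from .molevol import MKTable, SENSE_CODONS, _CODON_TABLE, _STOPS, ng86_site_counts

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_FAMILIES = [
    ("Tad1-like", "LINE"),
    ("Gypsy3", "LTR"),
    ("Pogo-like", "DNA"),
    ("Copia1", "LTR"),
    ("Sly1-like", "DNA"),
    ("MarinerNi", "DNA"),
]


@dataclass
class SimulationParams:
    """Study conditions for the synthetic dataset.

    Branch lengths are expected substitutions per site. Defaults emulate a
    handful of closely related haploid strains (within-group diversity a
    few tenths of a percent), a driver haplotype split an order of
    magnitude deeper, an outgroup deeper still, ~30% GC repeat clusters in
    a ~50% GC genome, near-complete methylation of repeat cytosines and a
    several-fold IP enrichment over input in repeats.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000, "chr3": 120_000}
    )
    region: tuple[str, int, int] = ("chr3", 25_000, 60_000)
    n_sensitive: int = 9
    n_killer_a: int = 4
    n_killer_b: int = 1
    n_outgroup: int = 2
    theta: float = 0.002            # pendant branch, within-group
    killer_split: float = 0.03      # stem of the driver-A clade in the region
    killer_b_depth: float = 0.03    # extra depth of the lone driver-B strain
    outgroup_depth: float = 0.06    # stem of the outgroup clade
    tracts: list[tuple[str, int, int]] = field(default_factory=list)
    strict_tracts: bool = True
    n_genes_region: int = 8
    n_genes_background: int = 20
    gene_length: int = 900          # bp, multiple of 3
    omega: float = 0.2              # nonsynonymous/synonymous intensity
    mean_syn_poly: float = 6.0      # expected synonymous polymorphisms per gene
    mean_syn_div: float = 12.0      # expected synonymous fixed differences per gene
    repeat_gc: float = 0.30
    background_gc: float = 0.50
    n_repeats_region: int = 5
    n_repeats_background: int = 3
    repeat_length: int = 4_000
    meth_repeat: float = 0.9
    meth_background: float = 0.02
    meth_depth: float = 20.0
    cytosine_keep: float = 0.25     # fraction of reference C positions reported
    input_depth: float = 20.0
    ip_fold_repeat: float = 6.0
    coverage_bin: int = 50

    @property
    def sensitives(self) -> list[str]:
        return [f"S{i+1:02d}" for i in range(self.n_sensitive)]

    @property
    def killers_a(self) -> list[str]:
        return [f"KA{i+1}" for i in range(self.n_killer_a)]

    @property
    def killers_b(self) -> list[str]:
        return [f"KB{i+1}" for i in range(self.n_killer_b)]

    @property
    def outgroups(self) -> list[str]:
        return [f"O{i+1}" for i in range(self.n_outgroup)]

    @property
    def samples(self) -> list[str]:
        return self.sensitives + self.killers_a + self.killers_b + self.outgroups

    @property
    def ingroup(self) -> list[str]:
        return self.sensitives + self.killers_a + self.killers_b


@dataclass
class TruthRecord:
    region: tuple[str, int, int]
    tracts: list[dict]
    genes: list[dict]
    repeats: list[dict]
    samples: dict[str, list[str]]
    params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genealogy machinery
# ---------------------------------------------------------------------------

def _branches_region(p: SimulationParams) -> list[tuple[list[str], float]]:
    """(carrier set, branch length) pairs for the non-recombining region."""
    b: list[tuple[list[str], float]] = []
    b.append((p.killers_a, p.killer_split))
    for s in p.killers_a:
        b.append(([s], p.theta))
    for s in p.killers_b:
        b.append(([s], p.theta + p.killer_b_depth))
    for s in p.sensitives:
        b.append(([s], p.theta))
    b.append((p.outgroups, p.outgroup_depth))
    for s in p.outgroups:
        b.append(([s], p.theta))
    return b


def _branches_background(p: SimulationParams) -> list[tuple[list[str], float]]:
    """Star-like background genealogy: the drivers were repeatedly
    backcrossed into the sensitive background, so outside the region every
    ingroup strain hangs off the same star."""
    b: list[tuple[list[str], float]] = []
    for s in p.ingroup:
        b.append(([s], p.theta))
    b.append((p.outgroups, p.outgroup_depth))
    for s in p.outgroups:
        b.append(([s], p.theta))
    return b


def _plant_segment(
    rng: np.random.Generator,
    candidates: np.ndarray,
    branches: list[tuple[list[str], float]],
    sample_index: dict[str, int],
    n_samples: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson mutations on a fixed genealogy over candidate positions.

    Returns (positions, derived-carrier boolean matrix, derived offsets);
    infinite-sites: each candidate position is used at most once.
    """
    pool = candidates.copy()
    rng.shuffle(pool)
    used = 0
    rows = []
    for carriers, length in branches:
        m = rng.poisson(length * candidates.size)
        m = min(m, pool.size - used)
        mask = np.zeros(n_samples, dtype=bool)
        mask[[sample_index[s] for s in carriers]] = True
        for pos in pool[used : used + m]:
            rows.append((int(pos), mask))
        used += m
    rows.sort(key=lambda r: r[0])
    if not rows:
        return (
            np.empty(0, dtype=np.int64),
            np.empty((n_samples, 0), dtype=bool),
            np.empty(0, dtype=np.int64),
        )
    positions = np.array([r[0] for r in rows], dtype=np.int64)
    carriers = np.stack([r[1] for r in rows], axis=1)
    offsets = rng.integers(1, 4, size=positions.size)  # derived = ref + offset mod 4
    return positions, carriers, offsets


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _free_gaps(length: int, blocked: list[tuple[int, int]], lo: int = 0, hi: int | None = None):
    hi = length if hi is None else hi
    gaps = []
    cur = lo
    for s, e in sorted(blocked):
        if s > cur:
            gaps.append((cur, min(s, hi)))
        cur = max(cur, e)
        if cur >= hi:
            break
    if cur < hi:
        gaps.append((cur, hi))
    return [(s, e) for s, e in gaps if e - s > 0]


def _place(gaps, n: int, size: int, spacing: int) -> list[int]:
    starts = []
    for s, e in gaps:
        pos = s + spacing
        while pos + size + spacing <= e and len(starts) < n:
            starts.append(pos)
            pos += size + spacing
        if len(starts) >= n:
            break
    if len(starts) < n:
        raise ValueError(f"cannot place {n} features of {size} bp")
    return starts


# ---------------------------------------------------------------------------
# coding mutation planting
# ---------------------------------------------------------------------------

def _codon_candidates(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """Single-nucleotide, non-stop changes of the requested class."""
    aa = _CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            if (_CODON_TABLE[mut] == aa) == synonymous:
                out.append((pos, b))
    return out


def _plant_coding(
    rng: np.random.Generator,
    cds: str,
    n_syn_poly: int,
    n_nonsyn_poly: int,
    n_syn_div: int,
    n_nonsyn_div: int,
    n_ingroup: int,
):
    """Choose codon positions and substitutions of exact NG86 class.

    Returns a list of (cds_offset, derived_base, kind, carrier_subset_size)
    where kind is one of psyn/pnon/dsyn/dnon; one mutation per codon so
    classifications never interact.
    """
    n_codons = len(cds) // 3
    order = rng.permutation(n_codons)
    jobs = (
        [("psyn", True)] * n_syn_poly
        + [("pnon", False)] * n_nonsyn_poly
        + [("dsyn", True)] * n_syn_div
        + [("dnon", False)] * n_nonsyn_div
    )
    out = []
    cursor = 0
    for kind, synonymous in jobs:
        placed = False
        while cursor < n_codons:
            ci = int(order[cursor])
            cursor += 1
            codon = cds[3 * ci : 3 * ci + 3]
            cands = _codon_candidates(codon, synonymous)
            if not cands:
                continue
            pos, base = cands[int(rng.integers(0, len(cands)))]
            subset = int(rng.integers(1, n_ingroup)) if kind.startswith("p") else 0
            out.append((3 * ci + pos, base, kind, subset))
            placed = True
            break
        if not placed:
            log.warning("gene too short to place all planted mutations")
            break
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate(params: SimulationParams, outdir) -> tuple[dict[str, Path], TruthRecord]:
    """Write the full synthetic dataset to ``outdir``; same seed, same bytes.

    Emits reference FASTA, haploid VCF of all samples, GFF3 gene models,
    a RepeatMasker-style repeat table, a counts-dialect methylation
    bedGraph, IP and input coverage bedGraphs and a truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    chrom_r, r_start, r_end = params.region
    if chrom_r not in params.chrom_lengths:
        raise ValueError(f"region chromosome {chrom_r!r} not declared")
    for sample, t_start, t_end in params.tracts:
        if params.strict_tracts and not (r_start <= t_start < t_end <= r_end):
            raise ValueError(f"tract {sample}:{t_start}-{t_end} outside region")

    samples = params.samples
    sample_index = {s: i for i, s in enumerate(samples)}
    n = len(samples)

    # ---- layout: repeats then genes -------------------------------------
    repeats: list[dict] = []
    repeat_by_chrom: dict[str, list[tuple[int, int]]] = {
        c: [] for c in params.chrom_lengths
    }
    region_len = r_end - r_start
    step = region_len // params.n_repeats_region
    for i in range(params.n_repeats_region):
        start = r_start + 1000 + i * step
        end = start + params.repeat_length
        fam, cls = _FAMILIES[i % 2]  # region clusters biased to two families
        repeats.append({"chrom": chrom_r, "start": start, "end": end,
                        "family": fam, "class": cls})
        repeat_by_chrom[chrom_r].append((start, end))
    bg_chrom = next(c for c in params.chrom_lengths if c != chrom_r)
    bg_len = params.chrom_lengths[bg_chrom]
    step = bg_len // (params.n_repeats_background + 1)
    for i in range(params.n_repeats_background):
        start = step * (i + 1)
        end = start + params.repeat_length
        fam, cls = _FAMILIES[2 + i % 4]
        repeats.append({"chrom": bg_chrom, "start": start, "end": end,
                        "family": fam, "class": cls})
        repeat_by_chrom[bg_chrom].append((start, end))

    gene_specs: list[dict] = []
    region_gaps = _free_gaps(
        params.chrom_lengths[chrom_r], repeat_by_chrom[chrom_r], r_start, r_end
    )
    for i, start in enumerate(
        _place(region_gaps, params.n_genes_region, params.gene_length, 300)
    ):
        gene_specs.append(
            {"id": f"g_region_{i+1:02d}", "chrom": chrom_r, "start": start,
             "end": start + params.gene_length,
             "strand": "-" if i % 3 == 2 else "+", "partition": "region"}
        )
    bg_gaps = _free_gaps(bg_len, repeat_by_chrom[bg_chrom])
    for i, start in enumerate(
        _place(bg_gaps, params.n_genes_background, params.gene_length, 300)
    ):
        gene_specs.append(
            {"id": f"g_bg_{i+1:02d}", "chrom": bg_chrom, "start": start,
             "end": start + params.gene_length,
             "strand": "-" if i % 3 == 2 else "+", "partition": bg_chrom}
        )

    # ---- reference sequences --------------------------------------------
    def draw_seq(length: int, gc: float) -> np.ndarray:
        pr = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
        return rng.choice(4, size=length, p=pr).astype(np.int8)

    ref: dict[str, np.ndarray] = {}
    for chrom, length in params.chrom_lengths.items():
        ref[chrom] = draw_seq(length, params.background_gc)
    for rep in repeats:
        ref[rep["chrom"]][rep["start"] : rep["end"]] = draw_seq(
            rep["end"] - rep["start"], params.repeat_gc
        )
    for g in gene_specs:
        codons = rng.choice(len(SENSE_CODONS), size=params.gene_length // 3)
        cds = "".join(SENSE_CODONS[c] for c in codons)
        g["cds"] = cds
        genomic = cds if g["strand"] == "+" else "".join(
            _COMPLEMENT[b] for b in reversed(cds)
        )
        ref[g["chrom"]][g["start"] : g["end"]] = [BASE_CODE[ch] for ch in genomic]

    cds_blocked = {
        c: [(g["start"], g["end"]) for g in gene_specs if g["chrom"] == c]
        for c in params.chrom_lengths
    }

    # ---- genealogy mutations (non-coding) -------------------------------
    records: dict[str, list[tuple[int, int, int, np.ndarray]]] = {
        c: [] for c in params.chrom_lengths
    }  # (pos, ref_code, alt_code, carrier mask)

    def segment_candidates(chrom: str, lo: int, hi: int) -> np.ndarray:
        blocked = sorted(cds_blocked[chrom])
        mask = np.ones(hi - lo, dtype=bool)
        for s, e in blocked:
            s2, e2 = max(s, lo), min(e, hi)
            if s2 < e2:
                mask[s2 - lo : e2 - lo] = False
        return np.arange(lo, hi, dtype=np.int64)[mask]

    segments: list[tuple[str, int, int, list]] = []
    for chrom, length in params.chrom_lengths.items():
        if chrom == chrom_r:
            if r_start > 0:
                segments.append((chrom, 0, r_start, _branches_background(params)))
            segments.append((chrom, r_start, r_end, _branches_region(params)))
            if r_end < length:
                segments.append((chrom, r_end, length, _branches_background(params)))
        else:
            segments.append((chrom, 0, length, _branches_background(params)))

    for chrom, lo, hi, branches in segments:
        cand = segment_candidates(chrom, lo, hi)
        pos, carriers, offsets = _plant_segment(rng, cand, branches, sample_index, n)
        for j in range(pos.size):
            ref_code = int(ref[chrom][pos[j]])
            alt_code = (ref_code + int(offsets[j])) % 4
            records[chrom].append((int(pos[j]), ref_code, alt_code, carriers[:, j]))

    # ---- planted introgression tracts -----------------------------------
    realized_tracts = []
    for sample, t_start, t_end in params.tracts:
        si = sample_index[sample]
        t0, t1 = max(t_start, r_start), min(t_end, r_end)
        n_cleared = 0
        for pos, _, _, mask in records[chrom_r]:
            if t0 <= pos < t1 and mask[si]:
                mask[si] = False  # copy of the sensitive consensus (= reference)
                n_cleared += 1
        realized_tracts.append(
            {"sample": sample, "chrom": chrom_r, "start": t0, "end": t1,
             "sites_converted": n_cleared}
        )

    # ---- planted coding variation ---------------------------------------
    n_ingroup = len(params.ingroup)
    ingroup_idx = [sample_index[s] for s in params.ingroup]
    outgroup_idx = [sample_index[s] for s in params.outgroups]
    for g in gene_specs:
        cds = g["cds"]
        n_sites, s_sites = 0.0, 0.0
        for i in range(len(cds) // 3):
            ni, si = ng86_site_counts(cds[3 * i : 3 * i + 3])
            n_sites += ni
            s_sites += si
        ratio = n_sites / s_sites
        ps = int(rng.poisson(params.mean_syn_poly))
        pn = int(rng.poisson(params.omega * params.mean_syn_poly * ratio))
        ds = int(rng.poisson(params.mean_syn_div))
        dn = int(rng.poisson(params.omega * params.mean_syn_div * ratio))
        planted = _plant_coding(rng, cds, ps, pn, ds, dn, n_ingroup)
        counts = {"psyn": 0, "pnon": 0, "dsyn": 0, "dnon": 0}
        for cds_off, base, kind, subset in planted:
            counts[kind] += 1
            if g["strand"] == "+":
                gpos = g["start"] + cds_off
                ref_b = cds[cds_off]
                alt_b = base
            else:
                gpos = g["end"] - 1 - cds_off
                ref_b = _COMPLEMENT[cds[cds_off]]
                alt_b = _COMPLEMENT[base]
            mask = np.zeros(n, dtype=bool)
            if kind.startswith("p"):
                chosen = rng.choice(ingroup_idx, size=subset, replace=False)
                mask[chosen] = True
            else:
                mask[outgroup_idx] = True
            records[g["chrom"]].append(
                (gpos, BASE_CODE[ref_b], BASE_CODE[alt_b], mask)
            )
        g["planted"] = {"p_n": counts["pnon"], "p_s": counts["psyn"],
                        "d_n": counts["dnon"], "d_s": counts["dsyn"]}

    # ---- write outputs ---------------------------------------------------
    paths = {
        "fasta": outdir / "reference.fa",
        "vcf": outdir / "variants.vcf",
        "gff": outdir / "genes.gff3",
        "repeats": outdir / "repeats.out",
        "methylation": outdir / "methylation.bedgraph",
        "ip": outdir / "ip.bedgraph",
        "input": outdir / "input.bedgraph",
        "truth": outdir / "truth.json",
    }

    with open(paths["fasta"], "w") as fh:
        for chrom in params.chrom_lengths:
            seq = "".join(CODE_BASE[c] for c in ref[chrom])
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in params.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom in params.chrom_lengths:
            for pos, ref_c, alt_c, mask in sorted(records[chrom], key=lambda r: r[0]):
                gts = "\t".join("1" if m else "0" for m in mask)
                fh.write(f"{chrom}\t{pos+1}\t.\t{CODE_BASE[ref_c]}\t"
                         f"{CODE_BASE[alt_c]}\t.\tPASS\t.\tGT\t{gts}\n")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_specs:
            s, e = g["start"] + 1, g["end"]  # GFF is 1-based inclusive
            fh.write(f"{g['chrom']}\tsim\tgene\t{s}\t{e}\t.\t{g['strand']}\t."
                     f"\tID={g['id']}\n")
            fh.write(f"{g['chrom']}\tsim\tmRNA\t{s}\t{e}\t.\t{g['strand']}\t."
                     f"\tID={g['id']}.t1;Parent={g['id']}\n")
            fh.write(f"{g['chrom']}\tsim\tCDS\t{s}\t{e}\t.\t{g['strand']}\t0"
                     f"\tID={g['id']}.cds;Parent={g['id']}.t1\n")

    with open(paths["repeats"], "w") as fh:
        fh.write("   SW  perc perc perc  query     position in query    matching"
                 "  repeat        position in repeat\n")
        fh.write("score  div. del. ins.  sequence  begin end   (left)   repeat"
                 "  class/family  begin end (left) ID\n\n")
        for i, rep in enumerate(repeats, 1):
            fh.write(f"  500  10.0  0.0  0.0  {rep['chrom']}  {rep['start']+1} "
                     f"{rep['end']}  (0)  +  {rep['family']}  {rep['class']}  "
                     f"1  {rep['end']-rep['start']}  (0)  {i}\n")

    repeat_lookup = {
        c: sorted(ivs) for c, ivs in repeat_by_chrom.items()
    }

    def in_repeat(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in repeat_lookup[chrom])

    with open(paths["methylation"], "w") as fh:
        for chrom in params.chrom_lengths:
            c_pos = np.flatnonzero(ref[chrom] == BASE_CODE["C"])
            keep = rng.random(c_pos.size) < params.cytosine_keep
            for pos in c_pos[keep]:
                level = (
                    params.meth_repeat
                    if in_repeat(chrom, int(pos))
                    else params.meth_background
                )
                total = int(rng.poisson(params.meth_depth)) + 1
                meth = int(rng.binomial(total, level))
                pct = 100.0 * meth / total
                fh.write(f"{chrom}\t{pos}\t{pos+1}\t{pct:.4f}\t{meth}\t{total-meth}\n")

    with open(paths["ip"], "w") as fh_ip, open(paths["input"], "w") as fh_in:
        for chrom, length in params.chrom_lengths.items():
            for start in range(0, length, params.coverage_bin):
                end = min(start + params.coverage_bin, length)
                mid = (start + end) // 2
                base = params.input_depth
                ip_mean = base * (
                    params.ip_fold_repeat if in_repeat(chrom, mid) else 1.0
                )
                fh_in.write(f"{chrom}\t{start}\t{end}\t{rng.poisson(base)}\n")
                fh_ip.write(f"{chrom}\t{start}\t{end}\t{rng.poisson(ip_mean)}\n")

    truth = TruthRecord(
        region=params.region,
        tracts=realized_tracts,
        genes=[
            {k: g[k] for k in ("id", "chrom", "start", "end", "strand",
                               "partition", "planted")}
            for g in gene_specs
        ],
        repeats=repeats,
        samples={
            "sensitive": params.sensitives,
            "killer_a": params.killers_a,
            "killer_b": params.killers_b,
            "outgroup": params.outgroups,
        },
        params={
            k: v for k, v in asdict(params).items() if k != "chrom_lengths"
        } | {"chrom_lengths": dict(params.chrom_lengths)},
    )
    truth.to_json(paths["truth"])
    return paths, truth


# ---------------------------------------------------------------------------
# fast matrix-only simulation (no disk) for scanner studies
# ---------------------------------------------------------------------------

def simulate_scan_matrix(
    params: SimulationParams, seed: int | None = None
) -> VariantMatrix:
    """Variant matrix of the non-recombining region only (no files, no
    genes): the fast path for repeated scanner-recovery experiments."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    chrom, r_start, r_end = params.region
    samples = params.samples
    sample_index = {s: i for i, s in enumerate(samples)}
    cand = np.arange(r_start, r_end, dtype=np.int64)
    pos, carriers, offsets = _plant_segment(
        rng, cand, _branches_region(params), sample_index, len(samples)
    )
    ref_codes = rng.integers(0, 4, size=pos.size)
    alt_codes = (ref_codes + offsets) % 4
    for sample, t_start, t_end in params.tracts:
        si = sample_index[sample]
        inside = (pos >= max(t_start, r_start)) & (pos < min(t_end, r_end))
        carriers[si, inside] = False
    alleles = np.where(carriers, alt_codes[None, :], ref_codes[None, :]).astype(np.int8)
    return VariantMatrix(
        samples=list(samples),
        positions={chrom: pos},
        alleles={chrom: alleles},
        ref={chrom: ref_codes.astype(np.int8)},
        alt={chrom: alt_codes.astype(np.int8)},
    )


# ---------------------------------------------------------------------------
# published benchmark MK counts
# ---------------------------------------------------------------------------

def reference_mk_tables() -> dict[str, MKTable]:
    """Published pooled McDonald–Kreitman counts for the fungal
    meiotic-drive system this package targets: genome-wide totals, four
    individual chromosomes and the non-recombining drive region. Used as a
    frozen regression fixture for ratio arithmetic; returns fresh objects
    on every call."""
    rows = {
        "total": (58_830, 153_013, 59_077, 132_834),
        "chr1": (12_349, 31_767, 14_403, 30_655),
        "chr2": (6_571, 17_813, 6_003, 13_624),
        "chr3": (5_293, 13_168, 4_897, 10_775),
        "chr7": (7_748, 18_962, 7_391, 15_567),
        "sk_region": (770, 1_499, 2_985, 7_360),
    }
    return {k: MKTable(*v) for k, v in rows.items()}
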