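"""Standard-format I/O: FASTA, haploid VCF, GFF3, RepeatMasker tables and
bedGraph tracks, converted once to the internal 0-based half-open model."""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BASE_CODE,
    CODE_BASE,
    MISSING,
    FormatError,
    GeneModel,
    GenomeSequence,
    Interval,
    RepeatAnnotation,
    SignalTrack,
    VariantMatrix,
)

log = logging.getLogger(__name__)

_VALID = set("ACGTN")


class ConfigurationError(ValueError):
    """Input violates an analysis assumption (e.g. diploid genotypes)."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    """Read a genome FASTA; sequences are uppercased and any character
    outside {A,C,G,T,N} is mapped to N (the substitution count is logged)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or malformed FASTA")
    sequences: dict[str, str] = {}
    n_sub = 0
    for rec in records:
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in _VALID else "N" for c in seq)
        n_sub += sum(1 for a, b in zip(seq, cleaned) if a != b)
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate chromosome {rec.id!r}")
        sequences[rec.id] = cleaned
    if n_sub:
        log.info("%s: mapped %d non-ACGTN characters to N", path, n_sub)
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF (haploid genotypes)
# ---------------------------------------------------------------------------

def read_variants(path) -> VariantMatrix:
    """Read a haploid VCF into a :class:`VariantMatrix`.

    Only biallelic SNP records are retained; indels and multi-allelic
    records are dropped and counted. A "." genotype becomes the missing
    code. A diploid genotype is a configuration error naming the sample.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    positions: dict[str, list[int]] = {}
    alleles: dict[str, list[np.ndarray]] = {}
    refs: dict[str, list[int]] = {}
    alts: dict[str, list[int]] = {}
    n_dropped = 0
    for rec in vf:
        alts_rec = rec.alts or ()
        if (
            len(alts_rec) != 1
            or len(rec.ref) != 1
            or len(alts_rec[0]) != 1
            or rec.ref.upper() not in BASE_CODE
            or alts_rec[0].upper() not in BASE_CODE
        ):
            n_dropped += 1
            continue
        ref_code = BASE_CODE[rec.ref.upper()]
        alt_code = BASE_CODE[alts_rec[0].upper()]
        row = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if len(gt) > 1:
                raise ConfigurationError(
                    f"{path}: diploid genotype for sample {s!r} at "
                    f"{rec.chrom}:{rec.pos}"
                )
            a = gt[0]
            if a is None:
                row[i] = MISSING
            elif a == 0:
                row[i] = ref_code
            elif a == 1:
                row[i] = alt_code
            else:
                raise FormatError(
                    f"{path}: allele index {a} out of range at "
                    f"{rec.chrom}:{rec.pos}"
                )
        chrom = rec.chrom
        positions.setdefault(chrom, []).append(rec.pos - 1)  # VCF is 1-based
        alleles.setdefault(chrom, []).append(row)
        refs.setdefault(chrom, []).append(ref_code)
        alts.setdefault(chrom, []).append(alt_code)
    if n_dropped:
        log.info("%s: dropped %d non-biallelic-SNP records", path, n_dropped)
    return VariantMatrix(
        samples=samples,
        positions={c: np.array(p, dtype=np.int64) for c, p in positions.items()},
        alleles={
            c: np.vstack(rows).T.copy() if rows else np.empty((len(samples), 0), np.int8)
            for c, rows in alleles.items()
        },
        ref={c: np.array(v, dtype=np.int8) for c, v in refs.items()},
        alt={c: np.array(v, dtype=np.int8) for c, v in alts.items()},
    )


def write_variants(
    vm: VariantMatrix, path, contig_lengths: dict[str, int] | None = None
) -> None:
    """Write a haploid VCF. Sites without stored ref/alt use the first
    observed allele as REF and the other observed allele as ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in vm.chromosomes:
            length = (
                contig_lengths[chrom]
                if contig_lengths
                else int(vm.positions[chrom][-1]) + 1 if vm.n_sites(chrom) else 1
            )
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vm.samples)
            + "\n"
        )
        for chrom in vm.chromosomes:
            pos = vm.positions[chrom]
            mat = vm.alleles[chrom]
            have_ra = chrom in vm.ref and chrom in vm.alt
            for j in range(pos.size):
                col = mat[:, j]
                if have_ra:
                    ref_c = int(vm.ref[chrom][j])
                    alt_c = int(vm.alt[chrom][j])
                else:
                    observed = [int(c) for c in col if c != MISSING]
                    uniq = sorted(set(observed))
                    ref_c = uniq[0]
                    alt_c = uniq[1] if len(uniq) > 1 else (ref_c + 1) % 4
                gts = []
                for c in col:
                    if c == MISSING:
                        gts.append(".")
                    elif c == ref_c:
                        gts.append("0")
                    elif c == alt_c:
                        gts.append("1")
                    else:
                        raise ValueError(
                            f"{chrom}:{pos[j]}: allele {CODE_BASE[c]} matches "
                            "neither REF nor ALT"
                        )
                fh.write(
                    f"{chrom}\t{int(pos[j]) + 1}\t.\t{CODE_BASE[ref_c]}\t"
                    f"{CODE_BASE[alt_c]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker / BED repeat annotations
# ---------------------------------------------------------------------------

def read_repeatmasker(path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker .out table (15 columns, 1-based inclusive) or a
    6-column BED fallback (chrom, start, end, family[/class], score, strand)."""
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    # detect dialect from the first non-blank line
    body = [ln for ln in lines if ln.strip()]
    if not body:
        return annotations
    is_rm = body[0].lstrip().lower().startswith(("sw", "score"))
    if is_rm:
        for lineno, line in enumerate(lines, 1):
            fields = line.split()
            if len(fields) < 11 or not fields[0].isdigit():
                continue  # header / separator lines
            chrom = fields[4]
            start = int(fields[5]) - 1
            end = int(fields[6])
            name = fields[9]
            rclass = fields[10]
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: bad coordinates")
            annotations.append(
                RepeatAnnotation(Interval(chrom, start, end), name, rclass)
            )
    else:
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else None
            family, _, rclass = name.partition("/")
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: bad coordinates")
            annotations.append(
                RepeatAnnotation(Interval(chrom, start, end, strand), family, rclass)
            )
    return annotations


def write_repeats_bed(repeats: Iterable[RepeatAnnotation], path) -> None:
    with open(path, "w") as fh:
        for rep in repeats:
            iv = rep.interval
            name = f"{rep.family}/{rep.repeat_class}" if rep.repeat_class else rep.family
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand or '+'}\n")


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def read_methylation(path, lengths: dict[str, int] | None = None) -> SignalTrack:
    """Read per-cytosine methylation calls.

    Two dialects are accepted: 4-column bedGraph (chrom start end fraction,
    stored as fraction over total 1) and 6-column count reports
    (chrom start end percent methylated_reads unmethylated_reads)."""
    positions: dict[str, list[int]] = {}
    meth: dict[str, list[float]] = {}
    total: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if lengths is not None and end > lengths.get(chrom, end):
                raise FormatError(f"{path}:{lineno}: coordinate beyond chromosome")
            if len(fields) >= 6:
                m = float(fields[4])
                t = m + float(fields[5])
            elif len(fields) == 4:
                m = float(fields[3])
                t = 1.0
            else:
                raise FormatError(f"{path}:{lineno}: expected 4 or 6 columns")
            for p in range(start, end):
                positions.setdefault(chrom, []).append(p)
                meth.setdefault(chrom, []).append(m)
                total.setdefault(chrom, []).append(t)
    return SignalTrack(
        positions={c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        methylated={c: np.array(v, dtype=float) for c, v in meth.items()},
        total={c: np.array(v, dtype=float) for c, v in total.items()},
    )


def read_coverage(path, lengths: dict[str, int] | None = None) -> SignalTrack:
    """Read a depth bedGraph (chrom start end depth) as run-length intervals."""
    data: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: bad coordinates")
            if lengths is not None and end > lengths.get(chrom, end):
                raise FormatError(f"{path}:{lineno}: coordinate beyond chromosome")
            data.setdefault(chrom, []).append((start, end, value))
    intervals = {}
    for chrom, rows in data.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        intervals[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return SignalTrack(intervals=intervals)


def write_bedgraph(track_rows: Iterable[tuple[str, int, int, float]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff(path, lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Read gene models (gene -> mRNA -> CDS) from GFF3 via an in-memory DB."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds_features = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds_features:
            continue
        cds = []
        for f in cds_features:
            start, end = f.start - 1, f.end  # GFF is 1-based inclusive
            if lengths is not None and end > lengths.get(f.seqid, end):
                raise FormatError(
                    f"{path}: CDS of {gene.id} beyond chromosome {f.seqid}"
                )
            cds.append(Interval(f.seqid, start, end, f.strand))
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, cds))
    return genes
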