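"""End-to-end orchestration: one declarative config drives variant
filtering, the monophyly scan, repeat/chromatin window statistics, the
coding-sequence diversity/divergence analysis with its bootstrap null and,
optionally, the age bound. Each stage is independently invocable and all
outputs are plain TSV/JSON with a manifest recording seed and row counts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, io, molevol, phylo
from .core import (
    Interval,
    VariantMatrix,
    WindowTable,
    filter_variants,
    fixed_windows,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs
    fasta: str
    vcf: str
    gff: str | None = None
    repeats: str | None = None
    methylation: str | None = None
    ip_coverage: str | None = None
    input_coverage: str | None = None
    # sample roles
    focal: list[str] = field(default_factory=list)
    outgroup: list[str] = field(default_factory=list)
    anchor: str | None = None
    ingroup: list[str] = field(default_factory=list)  # for molevol; default: all non-outgroup
    # region
    region_chrom: str = ""
    region_start: int = 0
    region_end: int = 0
    # window parameters
    n_sites: int = 50
    bin_size: int = 50
    repeat_window: int = 2_000
    repeat_step: int = 2_000
    divergence_window: int = 10_000
    divergence_step: int = 2_000
    ci_step: int = 200_000
    repeat_threshold: float = 0.75
    # stats
    bootstrap_reps: int = 100
    scan_bootstrap_reps: int = 100
    seed: int = 0
    substitution_rate: float | None = None  # subs/site/year; required for the age stage
    divergence_pair: tuple[str, str] | None = None
    # output
    outdir: str = "sporekit_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class ConfigError(ValueError):
    pass


def _validate(cfg: PipelineConfig, vm: VariantMatrix, stages: set[str]) -> None:
    missing = [s for s in cfg.focal + cfg.outgroup if s not in vm.samples]
    if missing:
        raise ConfigError(f"samples not in VCF: {missing}")
    if "scan" in stages and (not cfg.focal or not cfg.outgroup):
        raise ConfigError("scan stage needs focal and outgroup sample ids")
    if cfg.region_chrom and cfg.region_chrom not in vm.positions:
        raise ConfigError(f"region chromosome {cfg.region_chrom!r} not in VCF")
    if "age" in stages and not cfg.substitution_rate:
        raise ConfigError(
            "substitution_rate is required for the age stage; set it in the config"
        )


def run(cfg: PipelineConfig, stages: set[str] | None = None) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Stages: filter, scan, repeats, chromatin, molevol, age (age only when a
    substitution rate is configured). Validation is fail-fast: configuration
    errors are raised before any compute starts.
    """
    all_stages = {"filter", "scan", "repeats", "chromatin", "molevol", "age"}
    if stages is None:
        stages = {"filter", "scan", "repeats", "chromatin", "molevol"}
        if cfg.substitution_rate:
            stages.add("age")
    unknown = stages - all_stages
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(cfg.fasta)
    vm = io.read_variants(cfg.vcf)
    _validate(cfg, vm, stages)
    repeats = io.read_repeatmasker(cfg.repeats) if cfg.repeats else []
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    region = (
        (cfg.region_chrom, cfg.region_start, cfg.region_end)
        if cfg.region_chrom
        else None
    )

    # ---- filter ----------------------------------------------------------
    if "filter" in stages:
        vm = filter_variants(vm, repeats)
        path = outdir / "filtered.vcf"
        io.write_variants(vm, path, genome.lengths)
        manifest["stages"]["filter"] = {
            "sites": {c: int(vm.n_sites(c)) for c in vm.chromosomes}
        }
        manifest["outputs"]["filtered_vcf"] = str(path)

    # ---- monophyly scan --------------------------------------------------
    if "scan" in stages:
        chrom = cfg.region_chrom or vm.chromosomes[0]
        calls, summary = phylo.scan_chromosome(
            vm,
            chrom,
            cfg.focal,
            cfg.outgroup,
            n_sites=cfg.n_sites,
            reps=cfg.scan_bootstrap_reps,
            bin_size=cfg.bin_size,
            anchor=cfg.anchor,
            seed=cfg.seed,
        )
        rows = [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "category": ",".join(sorted(c.category)),
                "support": "" if c.support is None else f"{c.support:.4f}",
            }
            for c in calls
        ]
        path = outdir / "monophyly_calls.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["monophyly_calls"] = str(path)
        bin_rows = []
        for b, (props, size) in enumerate(zip(summary.bins, summary.bin_sizes)):
            for cat, frac in sorted(props.items(), key=lambda kv: sorted(kv[0])):
                bin_rows.append(
                    {"bin": b, "size": size,
                     "category": ",".join(sorted(cat)), "proportion": frac}
                )
        path = outdir / "monophyly_bins.tsv"
        pd.DataFrame(bin_rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["monophyly_bins"] = str(path)
        manifest["stages"]["scan"] = {"windows": len(calls), "bins": len(summary.bins)}
        if cfg.divergence_pair:
            a, b = cfg.divergence_pair
            table = phylo.pairwise_divergence_scan(
                vm, chrom, a, b, genome.lengths[chrom],
                cfg.divergence_window, cfg.divergence_step,
            )
            path = outdir / "pairwise_divergence.tsv"
            table.to_tsv(path)
            manifest["outputs"]["pairwise_divergence"] = str(path)

    # ---- repeat / chromatin windows -------------------------------------
    if "repeats" in stages or "chromatin" in stages:
        windows: list[Interval] = []
        for chrom, length in genome.lengths.items():
            windows.extend(
                fixed_windows(chrom, length, cfg.repeat_window, cfg.repeat_step)
            )
        table = WindowTable.from_intervals(windows)
        fractions = chromatin.window_repeat_fraction(windows, repeats)
        labels = chromatin.classify_repeat_windows(fractions, cfg.repeat_threshold)
        table = table.with_column("repeat_fraction", fractions)
        table = table.with_column("window_class", [l.label for l in labels])
        table = table.with_column("gc", chromatin.window_gc(genome, windows))
        if "chromatin" in stages and cfg.methylation:
            meth = io.read_methylation(cfg.methylation, genome.lengths)
            table = table.with_column(
                "methylation_pct", chromatin.window_methylation(meth, windows)
            )
        if "chromatin" in stages and cfg.ip_coverage and cfg.input_coverage:
            ip = io.read_coverage(cfg.ip_coverage, genome.lengths)
            ctl = io.read_coverage(cfg.input_coverage, genome.lengths)
            table = table.with_column("chip_fold", chromatin.chip_fold(ip, ctl, windows))
        path = outdir / "window_table.tsv"
        table.to_tsv(path)
        manifest["outputs"]["window_table"] = str(path)
        manifest["stages"]["repeats"] = {"windows": len(windows)}

        summary_json: dict = {}
        frame = table.frame
        is_rep = frame["window_class"] == "repeat"
        for col in ("gc", "methylation_pct", "chip_fold"):
            if col not in frame or is_rep.sum() < 2 or (~is_rep).sum() < 2:
                continue
            cmp = chromatin.compare_groups(
                frame.loc[is_rep, col], frame.loc[~is_rep, col]
            )
            summary_json[f"{col}_repeat_vs_nonrepeat"] = {
                "t": cmp.t, "p": cmp.p,
                "mean_repeat": cmp.mean_a, "mean_non_repeat": cmp.mean_b,
            }
        if region is not None and repeats:
            chrom, start, end = region
            region_iv = Interval(chrom, start, end)
            region_reps = [
                r for r in repeats
                if r.interval.chrom == chrom and r.interval.overlaps(region_iv)
            ]
            genome_len = sum(genome.lengths.values())
            enr = chromatin.family_enrichment(
                region_reps, repeats, end - start, genome_len
            )
            summary_json["family_enrichment"] = [dataclasses.asdict(e) for e in enr]
            # region repeat fraction vs genome sliding windows of region size
            region_size = end - start
            ci_windows: list[Interval] = []
            for c, length in genome.lengths.items():
                step = min(cfg.ci_step, max(region_size // 4, 1))
                ci_windows.extend(fixed_windows(c, length, region_size, step))
            if len(ci_windows) >= 20:
                win_vals = chromatin.window_repeat_fraction(ci_windows, repeats)
                region_val = chromatin.window_repeat_fraction([region_iv], repeats)[0]
                ci = chromatin.region_vs_genome_ci(
                    win_vals, region_val, region_size, cfg.ci_step
                )
                summary_json["region_repeat_ci"] = dataclasses.asdict(ci)
        path = outdir / "chromatin_summary.json"
        with open(path, "w") as fh:
            json.dump(summary_json, fh, indent=1, sort_keys=True)
        manifest["outputs"]["chromatin_summary"] = str(path)
        manifest["stages"]["chromatin"] = {
            "comparisons": len([k for k in summary_json if k.endswith("nonrepeat")])
        }

    # ---- molecular evolution --------------------------------------------
    age_inputs = None
    if "molevol" in stages or "age" in stages:
        if not cfg.gff:
            raise ConfigError("molevol stage needs a GFF file")
        genes = io.read_gff(cfg.gff, genome.lengths)
        ingroup = cfg.ingroup or [
            s for s in vm.samples if s not in set(cfg.outgroup)
        ]
        stats_by_partition: dict[str, list[molevol.GeneStats]] = {}
        region_alns: dict[str, molevol.CodonAlignment] = {}
        for gene in genes:
            if not gene.valid:
                log.warning("%s: invalid CDS length; skipped", gene.gene_id)
                continue
            aln = molevol.build_codon_alignment(
                gene, genome, vm, ingroup, cfg.outgroup
            )
            try:
                gs = molevol.gene_stats(aln)
            except ValueError as exc:
                log.warning("%s skipped: %s", gene.gene_id, exc)
                continue
            part = molevol.assign_partition(gene, region)
            stats_by_partition.setdefault(part, []).append(gs)
            if part == "region":
                region_alns[gene.gene_id] = aln
        rows = []
        tables: dict[str, molevol.MKTable] = {}
        for part in sorted(stats_by_partition):
            div, mk = molevol.aggregate(stats_by_partition[part])
            tables[part] = mk
            ni = (
                molevol.neutrality_index(mk)
                if mk.p_s > 0 and mk.d_n > 0 and mk.d_s > 0
                else float("nan")
            )
            rows.append(
                {"partition": part, "pi_total": div.pi_total, "pi_n": div.pi_n,
                 "pi_s": div.pi_s,
                 "pi_n_over_pi_s": div.pi_n_over_pi_s,
                 "p_n": mk.p_n, "p_s": mk.p_s, "d_n": mk.d_n, "d_s": mk.d_s,
                 "pn_ps": mk.pn_ps, "dn_ds": mk.dn_ds, "ni": ni}
            )
        path = outdir / "molevol_table.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["molevol_table"] = str(path)
        manifest["stages"]["molevol"] = {
            "partitions": len(rows),
            "genes": sum(len(v) for v in stats_by_partition.values()),
        }

        if "region" in stats_by_partition:
            background = [
                g for part, lst in stats_by_partition.items()
                if part != "region"
                for g in lst
            ]
            region_genes = stats_by_partition["region"]
            region_length = sum(g.length for g in region_genes)
            _, region_mk = molevol.aggregate(region_genes)
            div, _ = molevol.aggregate(region_genes)
            observed = {
                "p_n": region_mk.p_n, "p_s": region_mk.p_s,
                "d_n": region_mk.d_n, "d_s": region_mk.d_s,
                "pi_n": div.pi_n, "pi_s": div.pi_s,
                "pi_n_over_pi_s": div.pi_n / div.pi_s if div.pi_s else float("nan"),
                "pn_ps": region_mk.pn_ps, "dn_ds": region_mk.dn_ds,
            }
            try:
                observed["ni"] = molevol.neutrality_index(region_mk)
            except ValueError:
                pass
            if background:
                null = molevol.bootstrap_null(
                    background,
                    len(region_genes),
                    region_length,
                    reps=max(cfg.bootstrap_reps, 100),
                    seed=cfg.seed,
                    observed=observed,
                )
                path = outdir / "bootstrap_null.json"
                with open(path, "w") as fh:
                    json.dump(
                        {
                            k: {"observed": v.observed, "lower": v.lower,
                                "upper": v.upper, "p": v.p_value, "reps": v.reps}
                            for k, v in null.items()
                        },
                        fh, indent=1, sort_keys=True,
                    )
                manifest["outputs"]["bootstrap_null"] = str(path)
            age_inputs = region_alns

    # ---- age bound -------------------------------------------------------
    if "age" in stages and age_inputs:
        sens = [s for s in (cfg.ingroup or vm.samples) if s not in cfg.focal
                and s not in cfg.outgroup and (cfg.anchor is None or s != cfg.anchor)]
        region_seqs = {}
        panel = {}
        for gid, aln in age_inputs.items():
            focal_in = [s for s in cfg.focal if s in aln.ingroup]
            if not focal_in:
                continue
            region_seqs[gid] = aln.ingroup[focal_in[0]]
            panel[gid] = {s: aln.ingroup[s] for s in sens if s in aln.ingroup}
        est = molevol.age_lower_bound(region_seqs, panel, cfg.substitution_rate)
        path = outdir / "age_estimate.json"
        with open(path, "w") as fh:
            json.dump(
                {"pooled_ds": est.pooled_ds, "age_years": est.age_years,
                 "subs_rate_per_year": est.subs_rate_per_year,
                 "per_gene_ds": est.per_gene_ds},
                fh, indent=1, sort_keys=True,
            )
        manifest["outputs"]["age_estimate"] = str(path)
        manifest["stages"]["age"] = {"genes": len(est.per_gene_ds)}

    # ---- manifest --------------------------------------------------------
    payload = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_sha256"] = hashlib.sha256(payload).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
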