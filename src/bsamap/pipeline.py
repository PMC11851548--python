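"""End-to-end orchestration: simulate → scan → annotate → stats → report.

A single YAML config drives the whole run; every stochastic step derives
from the one config seed, so a run is reproducible bit-for-bit.  Artifacts
are written with stable names into the output directory:

    variants.vcf, truth.tsv, reference.fa, genes.gff3,
    windows.tsv, peaks.bed, peaks.tsv, candidates.tsv, effects.tsv,
    segregation.tsv, report.md, scan_genome.png, scan_<chrom>.png
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from . import effector, genstats, scancore, simpop

log = logging.getLogger("bsamap")

__all__ = ["RunConfig", "MappingReport", "load_config", "run_pipeline", "plot_scan"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChromosomeCfg(_Strict):
    name: str
    length: int


class GenomeCfg(_Strict):
    # demo profile: a 25 Mb miniature genome; map density scaled up so the
    # causal linkage tract stays a small fraction of the genome (see the
    # benchmark module for the derivation)
    chromosomes: list[ChromosomeCfg] = [
        ChromosomeCfg(name=f"chr{i}", length=5_000_000) for i in range(1, 6)
    ]
    recombination_rate: float = 40.0


class CausalCfg(_Strict):
    chromosome: str = "chr3"
    position: int = 2_500_000
    effect: str = "frameshift"


class SimulateCfg(_Strict):
    ems_variant_count: int = 500
    indel_fraction: float = 0.1
    causal: CausalCfg | None = CausalCfg()
    bulk_size: int = 30
    mean_depth: float = 30.0
    sequencing_error: float = 0.002
    f3_family_size: int = 200
    n_families: int = 1


class FilterCfg(_Strict):
    min_depth: int = 20
    drop_parental_het: bool = False
    parental_het_band: tuple[float, float] = (0.35, 0.65)


class WindowCfg(_Strict):
    window: int = 500_000
    step: int = 10_000

    @model_validator(mode="after")
    def _check(self):
        if not self.window >= self.step > 0:
            raise ValueError("require window >= step > 0")
        return self


class ScanCfg(_Strict):
    k: float = 3.0
    delta_cutoff: float = 0.22
    vtype: Literal["SNP", "InDel", "both"] = "both"
    min_windows: int = 1
    lower_tail: bool = False


class RunConfig(_Strict):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    genome: GenomeCfg = GenomeCfg()
    simulate: SimulateCfg = SimulateCfg()
    filter: FilterCfg = FilterCfg()
    windows: WindowCfg = WindowCfg()
    scan: ScanCfg = ScanCfg()
    vcf: str | None = None  # user VCF: skip the simulate stage
    annotate: bool = True
    log_level: str = "INFO"

    def genome_spec(self) -> simpop.GenomeSpec:
        return simpop.GenomeSpec(
            chromosomes=tuple((c.name, c.length) for c in self.genome.chromosomes),
            recombination_rate=self.genome.recombination_rate,
            seed=self.seed,
        )

    def cross_design(self) -> simpop.CrossDesign:
        s = self.simulate
        causal = None
        if s.causal is not None:
            causal = (s.causal.chromosome, s.causal.position, s.causal.effect)
        return simpop.CrossDesign(
            ems_variant_count=s.ems_variant_count,
            indel_fraction=s.indel_fraction,
            causal=causal,
            bulk_size=s.bulk_size,
            mean_depth=s.mean_depth,
            sequencing_error=s.sequencing_error,
            f3_family_size=s.f3_family_size,
            n_families=s.n_families,
        )


class MappingReport(dict):
    """Report payload: peak table, candidates, segregation block, provenance."""


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path, plots: bool = True) -> MappingReport:
    """Execute all stages; returns the mapping report (also written as md)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    spec = config.genome_spec()
    report = MappingReport(
        provenance={"seed": config.seed, "config_sha256": _config_hash(config), "version": __version__}
    )

    # -- simulate ------------------------------------------------------------
    truth = None
    gene = None
    if config.vcf is None:
        log.info("stage simulate: %d EMS variants", config.simulate.ems_variant_count)
        design = config.cross_design()
        variants = simpop.generate_ems_variants(spec, design)
        truth = simpop.simulate_cross(spec, design, variants)
        bulks = simpop.make_bulks(truth, design, spec)
        table = simpop.sample_bulk_reads(truth, bulks, design, spec)
        simpop.write_truth_vcf(table, spec, outdir / "variants.vcf")
        simpop.write_truth_table(truth, outdir / "truth.tsv")
        if config.annotate and design.causal is not None:
            gene = simpop.make_causal_gene(design)
            simpop.write_reference_fasta(spec, variants, outdir / "reference.fa", gene=gene)
            simpop.write_gene_gff3(gene, outdir / "genes.gff3")
        vcf_path = outdir / "variants.vcf"
    else:
        vcf_path = Path(config.vcf)
        log.info("stage simulate: skipped (user VCF %s)", vcf_path)

    # -- scan ----------------------------------------------------------------
    log.info("stage scan: window=%d step=%d k=%.1f", config.windows.window, config.windows.step, config.scan.k)
    table = scancore.read_bulk_vcf(vcf_path)
    fspec = scancore.FilterSpec(
        min_depth=config.filter.min_depth,
        drop_parental_het=config.filter.drop_parental_het,
        parental_het_band=config.filter.parental_het_band,
    )
    filtered = scancore.filter_variants(table, fspec)
    wspec = scancore.WindowSpec(window=config.windows.window, step=config.windows.step)
    windows = scancore.sliding_windows(filtered, wspec, spec, vtype=config.scan.vtype)
    threshold = scancore.compute_threshold(filtered, k=config.scan.k, vtype=config.scan.vtype)
    peaks = scancore.call_peaks(
        windows, threshold, min_windows=config.scan.min_windows,
        table=filtered, lower_tail=config.scan.lower_tail,
    )
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False, float_format="%.6g")
    _write_peaks(peaks, threshold, outdir)

    # -- annotate ------------------------------------------------------------
    effects: dict[tuple[str, int], effector.VariantEffect] = {}
    if config.annotate and gene is not None:
        log.info("stage annotate: %d peak region(s)", len(peaks))
        import pyfaidx

        fa = pyfaidx.Fasta(str(outdir / "reference.fa"))
        # materialise chromosome strings once; per-variant slicing of the
        # indexed FASTA would re-read the sequence each time
        genome = {name: str(fa[name][:]) for name in fa.keys()}
        models = effector.read_gff3(outdir / "genes.gff3")
        model = models[gene["gene_id"]]
        ref_cds = effector.extract_cds(model, genome)
        for row in filtered.itertuples():
            eff = effector.annotate_variant(model, genome, (row.chrom, int(row.pos), row.ref, row.alt), ref_cds=ref_cds)
            effects[(row.chrom, int(row.pos))] = eff
    else:
        for row in filtered.itertuples():
            effects[(row.chrom, int(row.pos))] = effector.VariantEffect(None, "intergenic")
    eff_rows = [
        {"chrom": k[0], "pos": k[1], "gene": e.gene_id or ".", "category": e.category,
         "protein_change": e.protein_change, "truncated_at": e.truncated_at if e.truncated_at is not None else "."}
        for k, e in sorted(effects.items(), key=lambda kv: kv[0])
    ]
    pd.DataFrame(eff_rows).to_csv(outdir / "effects.tsv", sep="\t", index=False)

    candidates = []
    for region in peaks:
        cand = scancore.triage_candidates(region, filtered, effects, delta_cutoff=config.scan.delta_cutoff)
        cand = cand.assign(region=f"{region.chromosome}:{region.start}-{region.end}")
        candidates.append(cand)
    cand_df = (
        pd.concat(candidates, ignore_index=True)
        if candidates
        else pd.DataFrame(columns=list(filtered.columns) + ["category", "protein_changing", "region"])
    )
    cand_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False, float_format="%.6g")

    # -- stats ---------------------------------------------------------------
    seg = None
    if truth is not None:
        late = int((truth.phenotypes == "late").sum())
        normal = int((truth.phenotypes == "normal").sum())
        seg = genstats.chi_square_gof((normal, late), (3, 1))
        pd.DataFrame(
            [{"normal": normal, "late": late, "ratio": "3:1",
              "chi2": round(seg.chi2, 4), "df": seg.df, "p": round(seg.p, 4)}]
        ).to_csv(outdir / "segregation.tsv", sep="\t", index=False)

    # -- report --------------------------------------------------------------
    report.update(
        threshold={"mu": threshold.mu, "sigma": threshold.sigma, "k": threshold.k, "upper": threshold.upper},
        n_variants=int(len(table)),
        n_filtered=int(len(filtered)),
        peaks=[
            {"chrom": p.chromosome, "start": p.start, "end": p.end,
             "n_windows": p.n_windows, "max_mean_delta": p.max_mean_delta}
            for p in peaks
        ],
        candidates=cand_df,
        segregation=seg,
    )
    _write_report_md(report, outdir / "report.md")
    if plots:
        plot_scan(windows, threshold, peaks, outdir)
    log.info("done: %d peak(s), %d candidate(s)", len(peaks), len(cand_df))
    return report


def _write_peaks(peaks, threshold, outdir: Path) -> None:
    with open(outdir / "peaks.bed", "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\tpeak{i + 1}\t{p.max_mean_delta:.4f}\n")
    pd.DataFrame(
        [
            {"chrom": p.chromosome, "start": p.start, "end": p.end, "n_windows": p.n_windows,
             "max_mean_delta": round(p.max_mean_delta, 6), "threshold_upper": round(threshold.upper, 6)}
            for p in peaks
        ],
        columns=["chrom", "start", "end", "n_windows", "max_mean_delta", "threshold_upper"],
    ).to_csv(outdir / "peaks.tsv", sep="\t", index=False)


def _write_report_md(report: MappingReport, path: Path) -> None:
    lines = ["# Bulked-segregant mapping report", ""]
    prov = report["provenance"]
    lines += [f"- seed: {prov['seed']}", f"- config: sha256:{prov['config_sha256']}", f"- bsamap version: {prov['version']}", ""]
    th = report["threshold"]
    lines += [
        f"Variants: {report['n_variants']} total, {report['n_filtered']} after filtering.",
        f"Threshold: mean {th['mu']:.4f} + {th['k']:.0f}*SD {th['sigma']:.4f} = {th['upper']:.4f} (upper).",
        "", "## Peak regions", "",
    ]
    if report["peaks"]:
        lines.append("| chrom | start | end | windows | max mean ΔIndex |")
        lines.append("|---|---|---|---|---|")
        for p in report["peaks"]:
            lines.append(f"| {p['chrom']} | {p['start']} | {p['end']} | {p['n_windows']} | {p['max_mean_delta']:.4f} |")
    else:
        lines.append("No window exceeded the threshold.")
    lines += ["", "## Candidates", ""]
    cand = report["candidates"]
    if len(cand):
        lines.append("| chrom | pos | ref | alt | ΔIndex | category |")
        lines.append("|---|---|---|---|---|---|")
        for row in cand.itertuples():
            lines.append(f"| {row.chrom} | {row.pos} | {row.ref} | {row.alt} | {row.delta_index:.4f} | {row.category} |")
    else:
        lines.append("No candidate passed the ΔIndex cutoff.")
    seg = report.get("segregation")
    if seg is not None:
        lines += [
            "", "## Segregation", "",
            f"normal:late = {seg.observed[0]}:{seg.observed[1]} vs {seg.expected_ratio[0]:.0f}:{seg.expected_ratio[1]:.0f}, "
            f"chi2 = {seg.chi2:.4f}, df = {seg.df}, p = {seg.p:.4f}",
        ]
    path.write_text("\n".join(lines) + "\n")


def plot_scan(windows: pd.DataFrame, threshold, peaks, outdir: str | Path) -> list[Path]:
    """Genome-wide panel plus one panel per chromosome, with threshold line
    and shaded peak regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written = []
    chroms = list(windows.chrom.drop_duplicates())
    fig, axes = plt.subplots(1, len(chroms), figsize=(3 * len(chroms), 3), sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        _panel(ax, windows, threshold, peaks, chrom)
        ax.set_title(chrom)
    axes[0][0].set_ylabel("mean ΔIndex")
    fig.tight_layout()
    p = outdir / "scan_genome.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)
    for chrom in chroms:
        fig, ax = plt.subplots(figsize=(6, 3))
        _panel(ax, windows, threshold, peaks, chrom)
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("mean ΔIndex")
        fig.tight_layout()
        p = outdir / f"scan_{chrom}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written


def _panel(ax, windows, threshold, peaks, chrom) -> None:
    sub = windows[windows.chrom == chrom]
    mid = (sub.start + sub.end) / 2 / 1e6
    ax.plot(mid, sub.mean_delta, lw=0.8, color="tab:red")
    ax.axhline(threshold.upper, ls=":", color="brown", lw=1)
    ax.axhline(0, ls="-", color="grey", lw=0.5)
    for p in peaks:
        if p.chromosome == chrom:
            ax.axvspan(p.start / 1e6, p.end / 1e6, color="gold", alpha=0.3)
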