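"""SNP-index / ΔIndex genome scan: the mapping statistic of bulked-segregant
analysis for EMS mutants.

For every biallelic site the *index* of a bulk is the fraction of its reads
carrying the mutant (alternate) allele, ``alt / (alt + ref)``; ΔIndex is the
mutant-bulk index minus the wild-type-bulk index.  Around a recessive causal
variant the mutant bulk is fixed for the mutant allele (index → 1) while the
wild-type bulk, drawn from a 3:1-segregating family, sits near 1/3, so linked
variants show ΔIndex near 2/3 and unlinked variants near 0.  The scan
averages ΔIndex in sliding windows (default 0.5 Mb window, 10 kb step),
thresholds at the mean ± k·SD of all per-variant ΔIndex values (default
k = 3), and reports contiguous supra-threshold regions and their candidate
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .simpop import GenomeSpec

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "ThresholdSpec",
    "PeakRegion",
    "read_bulk_vcf",
    "compute_index",
    "add_indices",
    "filter_variants",
    "sliding_windows",
    "compute_threshold",
    "call_peaks",
    "triage_candidates",
    "genome_from_fai",
]

#: ranked above silent/noncoding consequences during candidate triage
PROTEIN_CHANGING = frozenset(
    {"stop_gained", "stop_lost", "frameshift", "missense", "inframe_deletion", "inframe_insertion"}
)


@dataclass(frozen=True)
class FilterSpec:
    """Variant filters applied before the scan.

    min_depth drops sites whose total read count in either bulk is below the
    cutoff (default 20 reads).  ``drop_parental_het`` additionally drops
    sites whose wild-type-bulk index falls inside ``parental_het_band`` — a
    proxy for loci heterozygous in the progenitor when no parental calls are
    available; off by default.
    """

    min_depth: int = 20
    drop_parental_het: bool = False
    parental_het_band: tuple[float, float] = (0.35, 0.65)

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        lo, hi = self.parental_het_band
        if not (0 <= lo <= hi <= 1):
            raise ValueError("parental_het_band must be an interval within [0, 1]")


@dataclass(frozen=True)
class WindowSpec:
    window: int = 500_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if not self.window >= self.step > 0:
            raise ValueError("require window >= step > 0")


@dataclass(frozen=True)
class ThresholdSpec:
    """mean ± k·SD of all per-variant ΔIndex values (sample SD, n−1)."""

    mu: float
    sigma: float
    k: float = 3.0

    @property
    def upper(self) -> float:
        return self.mu + self.k * self.sigma

    @property
    def lower(self) -> float:
        return self.mu - self.k * self.sigma


@dataclass
class PeakRegion:
    """A maximal run of consecutive supra-threshold windows, merged."""

    chromosome: str
    start: int  # 0-based half-open, union of member window spans
    end: int
    n_windows: int
    max_mean_delta: float
    variants: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    candidates: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# input


def read_bulk_vcf(
    path: str | Path,
    mut_sample: str = "MUT_BULK",
    wt_sample: str = "WT_BULK",
    skip_multiallelic: bool = True,
) -> pd.DataFrame:
    """Read a two-bulk VCF with per-sample AD into the bulk-variant table.

    One row per biallelic record with columns chrom, pos, ref, alt, vtype,
    is_causal (INFO/CAUSAL flag if present), per-bulk ref/alt depths, and
    the derived mut_index / wt_index / delta_index columns.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in (mut_sample, wt_sample):
            if s not in samples:
                raise ValueError(f"sample {s!r} not in VCF (has {samples})")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                if skip_multiallelic:
                    continue
                raise ValueError(f"multiallelic record at {rec.chrom}:{rec.pos}")
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "vtype": "InDel" if len(rec.ref) != len(rec.alts[0]) else "SNP",
                "is_causal": "CAUSAL" in rec.info,
            }
            for prefix, sample in (("mut", mut_sample), ("wt", wt_sample)):
                ad = rec.samples[sample].get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(f"missing AD for {sample} at {rec.chrom}:{rec.pos}")
                row[f"{prefix}_ref_depth"], row[f"{prefix}_alt_depth"] = int(ad[0]), int(ad[1])
            rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "vtype", "is_causal",
            "mut_ref_depth", "mut_alt_depth", "wt_ref_depth", "wt_alt_depth",
        ],
    )
    return add_indices(table)


def compute_index(ref_depth: int, alt_depth: int) -> float:
    """Bulk index at one site: alt / (alt + ref); NaN when both depths are 0."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("read depths must be non-negative")
    total = ref_depth + alt_depth
    return float("nan") if total == 0 else alt_depth / total


def add_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Attach mut_index, wt_index and delta_index columns (vectorised)."""
    table = table.copy()
    for prefix in ("mut", "wt"):
        ref = table[f"{prefix}_ref_depth"].to_numpy(dtype=float)
        alt = table[f"{prefix}_alt_depth"].to_numpy(dtype=float)
        if (ref < 0).any() or (alt < 0).any():
            raise ValueError("read depths must be non-negative")
        total = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            table[f"{prefix}_index"] = np.where(total > 0, alt / np.where(total > 0, total, 1), np.nan)
    table["delta_index"] = table["mut_index"] - table["wt_index"]
    return table


# ---------------------------------------------------------------------------
# filtering and windows


def filter_variants(table: pd.DataFrame, spec: FilterSpec = FilterSpec()) -> pd.DataFrame:
    """Apply depth and heterozygosity filters; order is preserved."""
    mut_total = table.mut_ref_depth + table.mut_alt_depth
    wt_total = table.wt_ref_depth + table.wt_alt_depth
    keep = (mut_total >= spec.min_depth) & (wt_total >= spec.min_depth)
    keep &= table.mut_index.notna() & table.wt_index.notna()
    if spec.drop_parental_het:
        lo, hi = spec.parental_het_band
        keep &= ~((table.wt_index >= lo) & (table.wt_index <= hi))
    return table[keep]


def _select_vtype(table: pd.DataFrame, vtype: str) -> pd.DataFrame:
    if vtype == "both":
        return table
    if vtype not in ("SNP", "InDel"):
        raise ValueError(f"vtype must be 'SNP', 'InDel' or 'both', got {vtype!r}")
    return table[table.vtype == vtype]


def sliding_windows(
    table: pd.DataFrame,
    spec: WindowSpec,
    genome: GenomeSpec,
    vtype: str = "both",
) -> pd.DataFrame:
    """Windowed mean ΔIndex along every chromosome.

    Windows are 0-based half-open, anchored at multiples of ``step`` from
    coordinate 0; full windows advance while start + window <= chromosome
    length, followed by at most one final window truncated at the chromosome
    end (when the last full window does not reach it).  A variant with
    1-based position p belongs to window [s, e) iff s < p <= e.  Returns a
    DataFrame with columns chrom, start, end, n_variants, mean_delta (NaN
    when empty).
    """
    table = _select_vtype(table, vtype)
    out = []
    for name, length in genome.chromosomes:
        sub = table[table.chrom == name].sort_values("pos")
        pos = sub.pos.to_numpy(dtype=float)
        delta = sub.delta_index.to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        if length >= spec.window:
            starts = np.arange(0, length - spec.window + 1, spec.step, dtype=int)
            if starts[-1] + spec.window < length:
                starts = np.append(starts, starts[-1] + spec.step)
        else:
            starts = np.array([0], dtype=int)
        ends = np.minimum(starts + spec.window, length)
        lo = np.searchsorted(pos, starts, side="right")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.where(n > 0, n, 1), np.nan)
        out.append(
            pd.DataFrame(
                {"chrom": name, "start": starts, "end": ends, "n_variants": n, "mean_delta": mean}
            )
        )
    return pd.concat(out, ignore_index=True)


def compute_threshold(table: pd.DataFrame, k: float = 3.0, vtype: str = "both") -> ThresholdSpec:
    """mean ± k·SD over *per-variant* ΔIndex values of the selected type."""
    deltas = _select_vtype(table, vtype).delta_index.dropna().to_numpy()
    if len(deltas) < 2:
        raise ValueError(f"need at least 2 defined delta_index values, have {len(deltas)}")
    return ThresholdSpec(mu=float(np.mean(deltas)), sigma=float(np.std(deltas, ddof=1)), k=k)


# ---------------------------------------------------------------------------
# peaks and candidates


def call_peaks(
    windows: pd.DataFrame,
    threshold: ThresholdSpec,
    min_windows: int = 1,
    table: pd.DataFrame | None = None,
    lower_tail: bool = False,
) -> list[PeakRegion]:
    """Merge maximal runs of consecutive supra-threshold windows into regions.

    By default only the upper tail (mean_delta > threshold.upper) is called:
    a recessive causal allele is enriched in the mutant bulk.  With
    ``lower_tail`` the mirrored rule (mean_delta < threshold.lower) is used.
    When ``table`` is given, each region carries its member variants.
    """
    peaks: list[PeakRegion] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if lower_tail:
            above = (sub.mean_delta < threshold.lower).to_numpy()
        else:
            above = (sub.mean_delta > threshold.upper).to_numpy()
        above &= sub.mean_delta.notna().to_numpy()
        if not above.any():
            continue
        # run-length encode the boolean track
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        runs = [
            (int(sub.start.iloc[i0]), int(sub.end.iloc[i1 - 1]), int(i1 - i0),
             float(sub.mean_delta.iloc[i0:i1].max()))
            for i0, i1 in zip(edges[::2], edges[1::2])
        ]
        # spans of nearby runs overlap (window >> step); merge them so
        # regions are non-overlapping
        merged: list[list] = []
        for start, end, n, mx in runs:
            if merged and start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] += n
                merged[-1][3] = max(merged[-1][3], mx)
            else:
                merged.append([start, end, n, mx])
        for start, end, n, mx in merged:
            if n < min_windows:
                continue
            region = PeakRegion(
                chromosome=str(chrom), start=start, end=end, n_windows=n, max_mean_delta=mx
            )
            if table is not None:
                in_region = (
                    (table.chrom == chrom)
                    & (table.pos > region.start)
                    & (table.pos <= region.end)
                )
                region.variants = table[in_region]
            peaks.append(region)
    peaks.sort(key=lambda p: (p.chromosome, p.start))
    return peaks


def triage_candidates(
    region: PeakRegion,
    table: pd.DataFrame,
    effects: Mapping[tuple[str, int], "object"],
    delta_cutoff: float = 0.22,
) -> pd.DataFrame:
    """Rank a peak region's variants into a candidate list.

    Keeps variants with delta_index > ``delta_cutoff`` (the in-region ΔIndex
    rule), joins each to its coding consequence, and ranks protein-changing
    consequences (stop_gained, frameshift, missense, in-frame indels) above
    silent/noncoding ones; ties break by descending delta_index then
    position.  ``effects`` maps (chrom, pos) to a VariantEffect or category
    string; a region variant absent from the map is an error.
    """
    in_region = (
        (table.chrom == region.chromosome)
        & (table.pos > region.start)
        & (table.pos <= region.end)
    )
    sub = table[in_region & (table.delta_index > delta_cutoff)].copy()
    categories = []
    for row in sub.itertuples():
        key = (row.chrom, int(row.pos))
        if key not in effects:
            raise KeyError(f"no effect annotation for variant {row.chrom}:{row.pos}")
        eff = effects[key]
        categories.append(getattr(eff, "category", eff))
    sub["category"] = categories
    sub["protein_changing"] = sub["category"].isin(PROTEIN_CHANGING)
    sub = sub.sort_values(
        ["protein_changing", "delta_index", "pos"], ascending=[False, False, True]
    ).reset_index(drop=True)
    region.candidates = sub
    return sub


def genome_from_fai(path: str | Path, recombination_rate: float = 4.0, seed: int = 0) -> GenomeSpec:
    """Build a GenomeSpec from a FASTA index (.fai) file."""
    fai = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["name", "length"])
    return GenomeSpec(
        chromosomes=tuple(zip(fai.name.astype(str), fai.length.astype(int))),
        recombination_rate=recombination_rate,
        seed=seed,
    )
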