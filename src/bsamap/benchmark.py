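"""Replicated simulation benchmarks of the mapping statistic.

Two in-memory experiment loops shared by the test suite, the analysis
drivers and the acceptance script:

* :func:`recovery_experiment` — the positive control: does the top peak
  region contain the planted causal variant, and does the causal site's
  ΔIndex match the Mendelian expectation of 2/3 (mutant-bulk index 1 versus
  wild-type-bulk index 1/3, since normal plants of a 3:1 family are 1/3
  homozygous wild type and 2/3 heterozygous)?
* :func:`null_experiment` — the negative control: with no causal variant the
  phenotype is noise and the mean ± 3·SD rule should call no peaks.

Both run the full simulate → filter → window → threshold → peak chain on the
default study conditions (5 × 5 Mb chromosomes, 500 EMS variants, one
3:1-segregating F3 family of 200, bulks of 30 at 30× depth, error 0.002)
without touching disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import scancore, simpop

__all__ = ["default_genome", "default_design", "run_scan_once", "recovery_experiment", "null_experiment"]


#: The demo genome is a miniature: 5 chromosomes x 5 Mb standing in for a
#: ~370 Mb rice genome.  Scaling the physical size down ~15x while keeping a
#: rice-like per-Mb map would make the whole causal chromosome co-segregate
#: (a geometry the real experiment never has), so the map density is scaled
#: up instead.  Two constraints pin it: the founder's heterozygous tract
#: around the causal locus, ~chrom_bp/(2*crossovers+1), must stay small
#: against the genome (else the mean+3SD threshold inflates) yet wide
#: against the 0.5 Mb scan window (else the peak dilutes).  Two crossovers
#: per gamete per chromosome (200 cM / 5 Mb -> 40 cM/Mb) gives a ~1 Mb
#: tract, ~4% of the genome, with the window inside it.
DEMO_RECOMBINATION_RATE = 40.0


def default_genome(seed: int) -> simpop.GenomeSpec:
    return simpop.GenomeSpec(
        chromosomes=tuple((f"chr{i}", 5_000_000) for i in range(1, 6)),
        recombination_rate=DEMO_RECOMBINATION_RATE,
        seed=seed,
    )


def default_design(causal: bool = True) -> simpop.CrossDesign:
    return simpop.CrossDesign(
        ems_variant_count=500,
        indel_fraction=0.1,
        causal=("chr3", 2_500_000, "frameshift") if causal else None,
        bulk_size=30,
        mean_depth=30.0,
        sequencing_error=0.002,
        f3_family_size=200,
    )


def run_scan_once(seed: int, causal: bool = True, k: float = 3.0, min_windows: int = 1):
    """One simulate→scan replicate.

    Returns (truth, raw indexed table, filtered table, peaks)."""
    spec = default_genome(seed)
    design = default_design(causal=causal)
    variants = simpop.generate_ems_variants(spec, design)
    truth = simpop.simulate_cross(spec, design, variants)
    bulks = simpop.make_bulks(truth, design, spec)
    table = scancore.add_indices(simpop.sample_bulk_reads(truth, bulks, design, spec))
    filtered = scancore.filter_variants(table, scancore.FilterSpec(min_depth=20))
    windows = scancore.sliding_windows(filtered, scancore.WindowSpec(), spec, vtype="both")
    threshold = scancore.compute_threshold(filtered, k=k, vtype="both")
    peaks = scancore.call_peaks(windows, threshold, min_windows=min_windows, table=filtered)
    return truth, table, filtered, peaks


def recovery_experiment(n_runs: int, base_seed: int = 0) -> pd.DataFrame:
    """Per-replicate recovery outcomes over ``n_runs`` seeded simulations.

    Columns: seed, causal_in_top_peak, causal_delta, causal_mut_index,
    n_peaks.  The top peak is the region with the largest max mean ΔIndex.
    """
    seeds = _child_seeds(base_seed, n_runs, stream=11)
    rows = []
    for seed in seeds:
        truth, table, filtered, peaks = run_scan_once(int(seed), causal=True)
        c_chrom, c_pos, _ = default_design().causal  # type: ignore[misc]
        hit = False
        if peaks:
            top = max(peaks, key=lambda p: p.max_mean_delta)
            hit = top.chromosome == c_chrom and top.start < c_pos <= top.end
        # ΔIndex expectation is a property of the read sampling, so it is
        # taken from the raw table (the depth filter would truncate it)
        causal_row = table[(table.chrom == c_chrom) & (table.pos == c_pos)]
        delta = float(causal_row.delta_index.iloc[0]) if len(causal_row) else np.nan
        mut_idx = float(causal_row.mut_index.iloc[0]) if len(causal_row) else np.nan
        rows.append(
            {"seed": int(seed), "causal_in_top_peak": hit, "causal_delta": delta,
             "causal_mut_index": mut_idx, "n_peaks": len(peaks)}
        )
    return pd.DataFrame(rows)


def null_experiment(n_runs: int, base_seed: int = 0, k: float = 3.0) -> pd.DataFrame:
    """Peak counts over ``n_runs`` null simulations (no causal variant)."""
    seeds = _child_seeds(base_seed, n_runs, stream=12)
    rows = []
    for seed in seeds:
        _, _, _, peaks = run_scan_once(int(seed), causal=False, k=k)
        rows.append({"seed": int(seed), "n_peaks": len(peaks)})
    return pd.DataFrame(rows)


def _child_seeds(base_seed: int, n: int, stream: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(stream,))
    return ss.generate_state(n) % (2**31)
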