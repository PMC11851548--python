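"""Forward simulation of an EMS bulked-segregant mapping experiment.

Emulates the standard MutMap-style study design for a recessive mutant in a
selfing crop: an EMS-mutagenised line is crossed back to its progenitor, the
F1 is selfed to give an F2, and an F2 plant heterozygous at the causal locus
founds an F3 family that segregates 3:1 for the mutant phenotype.  Two
phenotype bulks (mutant-like and wild-type-like) are drawn from that family
and "sequenced" by sampling per-site read depths, yielding a truth-annotated
variant table and VCF against which every downstream mapping stage can be
validated.

Genotypes are coded 0/1/2 copies of the mutant (EMS) allele.  Meiosis uses a
Poisson crossover process without interference (Haldane model): the expected
number of crossovers per chromosome is ``length_Mb * cM_per_Mb / 100`` and
crossover positions are uniform along the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "CrossDesign",
    "TruthSet",
    "generate_ems_variants",
    "simulate_cross",
    "make_bulks",
    "sample_bulk_reads",
    "write_truth_vcf",
    "write_truth_table",
    "write_reference_fasta",
    "make_causal_gene",
]

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout and a uniform genetic map.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    recombination_rate:
        Genetic map density in centimorgan per megabase (uniform along and
        across chromosomes).  4 cM/Mb is a rice-typical order of magnitude.
    seed:
        Root seed for every stochastic step derived from this genome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    recombination_rate: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length_of(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(name)


@dataclass(frozen=True)
class CrossDesign:
    """Experimental design of the cross and bulk sequencing.

    ``causal`` is ``(chromosome, position, effect_label)`` or ``None`` for a
    null design in which the phenotype is not genetically determined (late
    with probability 0.25, mirroring the segregation ratio but unlinked to
    any variant).
    """

    ems_variant_count: int = 500
    indel_fraction: float = 0.1
    causal: tuple[str, int, str] | None = ("chr3", 2_500_000, "frameshift")
    bulk_size: int = 30
    mean_depth: float = 30.0
    sequencing_error: float = 0.002
    f3_family_size: int = 200
    n_families: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.sequencing_error < 0.5:
            raise ValueError("sequencing_error must lie in [0, 0.5)")
        if self.bulk_size > self.f3_family_size * self.n_families:
            raise ValueError("bulk_size cannot exceed the F3 family size")
        if self.ems_variant_count < 1:
            raise ValueError("need at least one variant")


@dataclass
class TruthSet:
    """Planted ground truth of one simulated mapping population.

    ``variants`` is a DataFrame with columns chrom, pos, ref, alt, vtype,
    is_causal.  Genotype matrices are (individuals x variants) arrays of
    mutant-allele dosage in {0, 1, 2}; ``phenotypes`` holds "late"/"normal".
    """

    variants: pd.DataFrame
    causal_index: int | None
    f2_founder_genotypes: np.ndarray  # (n_families, n_variants)
    f3_genotypes: np.ndarray  # (n_individuals, n_variants)
    phenotypes: np.ndarray  # (n_individuals,) of "late" | "normal"
    family_of: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family_of is None:
            self.family_of = np.zeros(len(self.phenotypes), dtype=int)


# ---------------------------------------------------------------------------
# variant generation


def _rng(spec: GenomeSpec, stream: int) -> np.random.Generator:
    # one documented stream per pipeline stage, all derived from the root seed
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(stream,)))


def generate_ems_variants(spec: GenomeSpec, design: CrossDesign) -> pd.DataFrame:
    """Draw the EMS variant set over the genome.

    Positions are sampled without replacement, uniformly within each
    chromosome with chromosomes weighted by length.  SNVs follow the
    canonical EMS spectrum (G→A and C→T transitions); InDels are 1–12 bp
    insertions or deletions with a left anchor base, VCF-style.  The
    designated causal variant is forced into the list at its stated
    coordinates.

    Returns a DataFrame sorted by (chromosome order, position) with columns
    ``chrom, pos, ref, alt, vtype, is_causal``.
    """
    rng = _rng(spec, 1)
    if design.causal is not None:
        c_chrom, c_pos, _ = design.causal
        if c_chrom not in spec.names:
            raise ValueError(f"causal chromosome {c_chrom!r} not in genome")
        if not 1 <= c_pos <= spec.length_of(c_chrom):
            raise ValueError(
                f"causal position {c_chrom}:{c_pos} outside chromosome "
                f"(length {spec.length_of(c_chrom)})"
            )

    lengths = np.array([l for _, l in spec.chromosomes], dtype=float)
    n = design.ems_variant_count
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    rows: list[dict] = []
    # sample positions per chromosome without replacement, keeping a small
    # gap so that indel footprints never overlap
    for ci, (name, length) in enumerate(spec.chromosomes):
        k = int((chrom_idx == ci).sum())
        if k == 0:
            continue
        taken: set[int] = set()
        if design.causal is not None and design.causal[0] == name:
            taken.update(range(design.causal[1] - 13, design.causal[1] + 14))
        pos_list: list[int] = []
        while len(pos_list) < k:
            p = int(rng.integers(14, length - 13))
            if p in taken:
                continue
            taken.update(range(p - 13, p + 14))
            pos_list.append(p)
        for p in pos_list:
            rows.append(_draw_alleles(rng, name, p, design.indel_fraction))

    if design.causal is not None:
        c_chrom, c_pos, label = design.causal
        rows = [r for r in rows if not (r["chrom"] == c_chrom and r["pos"] == c_pos)]
        rows = rows[: n - 1]
        rows.append(_causal_alleles(rng, c_chrom, c_pos, label))
    else:
        rows = rows[:n]

    df = pd.DataFrame(rows)
    df["is_causal"] = False
    if design.causal is not None:
        df.loc[(df.chrom == design.causal[0]) & (df.pos == design.causal[1]), "is_causal"] = True
    order = {name: i for i, name in enumerate(spec.names)}
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    return df.reset_index(drop=True)


def _draw_alleles(rng: np.random.Generator, chrom: str, pos: int, indel_fraction: float) -> dict:
    if rng.random() < indel_fraction:
        size = int(rng.integers(1, 13))
        anchor = str(rng.choice(_DNA))
        inserted = "".join(rng.choice(_DNA, size=size))
        if rng.random() < 0.5:  # deletion
            ref, alt = anchor + inserted, anchor
        else:  # insertion
            ref, alt = anchor, anchor + inserted
        return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "vtype": "InDel"}
    # canonical EMS spectrum: G:C -> A:T transitions
    ref, alt = ("G", "A") if rng.random() < 0.5 else ("C", "T")
    return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "vtype": "SNP"}


def _causal_alleles(rng: np.random.Generator, chrom: str, pos: int, label: str) -> dict:
    if label in ("missense", "stop_gained", "synonymous"):
        ref, alt = ("G", "A") if rng.random() < 0.5 else ("C", "T")
        return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "vtype": "SNP"}
    # default: 1-bp frameshift deletion (in-frame labels get 3-bp deletions)
    size = 3 if label.startswith("inframe") else 1
    anchor = str(rng.choice(_DNA))
    removed = "".join(rng.choice(_DNA, size=size))
    return {"chrom": chrom, "pos": pos, "ref": anchor + removed, "alt": anchor, "vtype": "InDel"}


# ---------------------------------------------------------------------------
# meiosis and the cross


def _gamete(
    rng: np.random.Generator,
    hapA: np.ndarray,
    hapB: np.ndarray,
    positions: np.ndarray,
    length_bp: int,
    rate_cm_per_mb: float,
) -> np.ndarray:
    """One recombinant gamete for one chromosome.

    Crossover count ~ Poisson(length_Mb * rate / 100); positions uniform
    (Haldane, no interference).  The allele at each variant position comes
    from hapA or hapB according to the parity of crossovers to its left.
    """
    lam = length_bp / 1e6 * rate_cm_per_mb / 100.0
    k = rng.poisson(lam)
    start = rng.integers(2)
    if k == 0:
        return hapA if start == 0 else hapB
    breaks = np.sort(rng.uniform(0, length_bp, size=k))
    parity = (start + np.searchsorted(breaks, positions)) % 2
    return np.where(parity == 0, hapA, hapB)


def _self_offspring(
    rng: np.random.Generator,
    parent_haps: list[tuple[np.ndarray, np.ndarray]],
    pos_by_chrom: list[np.ndarray],
    spec: GenomeSpec,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Two gametes from selfing; returns per-chromosome haplotype pairs."""
    out = []
    for (hA, hB), positions, (_, length) in zip(parent_haps, pos_by_chrom, spec.chromosomes):
        g1 = _gamete(rng, hA, hB, positions, length, spec.recombination_rate)
        g2 = _gamete(rng, hA, hB, positions, length, spec.recombination_rate)
        out.append((g1, g2))
    return out


def simulate_cross(spec: GenomeSpec, design: CrossDesign, variants: pd.DataFrame) -> TruthSet:
    """Run the cross: F1 (het everywhere) → F2 founder → selfed F3 family.

    The F2 founder of each family is resampled until heterozygous at the
    causal locus, mirroring the selection of F3 families that segregate for
    the mutant phenotype.  Phenotypes are recessive: late iff dosage 2 at
    the causal variant.  With ``design.causal is None`` the founder is taken
    as-is and phenotypes are drawn independently (P(late) = 0.25).
    """
    rng = _rng(spec, 2)
    variants = variants.reset_index(drop=True)
    n_var = len(variants)
    causal_idx: int | None = None
    if design.causal is not None:
        hits = variants.index[variants.is_causal].tolist()
        if len(hits) != 1:
            raise ValueError(f"expected exactly one causal variant, found {len(hits)}")
        causal_idx = int(hits[0])

    pos_by_chrom: list[np.ndarray] = []
    col_by_chrom: list[np.ndarray] = []
    for name, _ in spec.chromosomes:
        mask = (variants.chrom == name).to_numpy()
        pos_by_chrom.append(variants.pos.to_numpy()[mask].astype(float))
        col_by_chrom.append(np.flatnonzero(mask))

    def flatten(haps: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
        geno = np.empty(n_var, dtype=np.int8)
        for (g1, g2), cols in zip(haps, col_by_chrom):
            geno[cols] = g1 + g2
        return geno

    # F1: one wild-type and one fully mutant haplotype per chromosome
    f1 = [
        (np.zeros(len(p), dtype=np.int8), np.ones(len(p), dtype=np.int8))
        for p in pos_by_chrom
    ]

    founders = []
    founder_geno = np.empty((design.n_families, n_var), dtype=np.int8)
    for fam in range(design.n_families):
        while True:
            f2 = _self_offspring(rng, f1, pos_by_chrom, spec)
            geno = flatten(f2)
            if causal_idx is None or geno[causal_idx] == 1:
                break
        founders.append(f2)
        founder_geno[fam] = geno

    n_per = design.f3_family_size
    f3_geno = np.empty((design.n_families * n_per, n_var), dtype=np.int8)
    family_of = np.repeat(np.arange(design.n_families), n_per)
    for fam, founder in enumerate(founders):
        for i in range(n_per):
            f3 = _self_offspring(rng, founder, pos_by_chrom, spec)
            f3_geno[fam * n_per + i] = flatten(f3)

    if causal_idx is not None:
        late = f3_geno[:, causal_idx] == 2
    else:
        late = rng.random(len(f3_geno)) < 0.25
    phenotypes = np.where(late, "late", "normal")

    return TruthSet(
        variants=variants,
        causal_index=causal_idx,
        f2_founder_genotypes=founder_geno,
        f3_genotypes=f3_geno,
        phenotypes=phenotypes,
        family_of=family_of,
    )


def make_bulks(truth: TruthSet, design: CrossDesign, spec: GenomeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two phenotype bulks (indices into the F3 family).

    ``bulk_size`` individuals are sampled without replacement from each
    phenotype class; the mutant bulk holds late plants, the wild-type bulk
    normal plants.
    """
    rng = _rng(spec, 3)
    late_idx = np.flatnonzero(truth.phenotypes == "late")
    normal_idx = np.flatnonzero(truth.phenotypes == "normal")
    for label, idx in (("late", late_idx), ("normal", normal_idx)):
        if len(idx) < design.bulk_size:
            raise ValueError(
                f"cannot form {label} bulk: need {design.bulk_size} plants, "
                f"have {len(idx)} (late={len(late_idx)}, normal={len(normal_idx)})"
            )
    mut_bulk = np.sort(rng.choice(late_idx, size=design.bulk_size, replace=False))
    wt_bulk = np.sort(rng.choice(normal_idx, size=design.bulk_size, replace=False))
    return mut_bulk, wt_bulk


def sample_bulk_reads(
    truth: TruthSet,
    bulks: tuple[np.ndarray, np.ndarray],
    design: CrossDesign,
    spec: GenomeSpec,
) -> pd.DataFrame:
    """Sample per-site read depths for both bulks.

    Per site and bulk the total depth is Poisson(mean_depth); each read
    carries the alternate allele with probability ``f(1-e) + (1-f)e`` where
    ``f`` is the bulk allele frequency (mean member dosage / 2) and ``e``
    the per-read error rate.

    Returns the bulk-variant table: the truth variant columns plus
    ``mut_ref_depth, mut_alt_depth, wt_ref_depth, wt_alt_depth``.
    """
    rng = _rng(spec, 4)
    table = truth.variants.copy()
    e = design.sequencing_error
    for prefix, members in zip(("mut", "wt"), bulks):
        freq = truth.f3_genotypes[members].mean(axis=0) / 2.0
        p_alt = freq * (1 - e) + (1 - freq) * e
        depth = rng.poisson(design.mean_depth, size=len(table))
        alt = rng.binomial(depth, p_alt)
        table[f"{prefix}_ref_depth"] = depth - alt
        table[f"{prefix}_alt_depth"] = alt
    return table


# ---------------------------------------------------------------------------
# output artifacts

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsamap.simpop
##INFO=<ID=CAUSAL,Number=0,Type=Flag,Description="Planted causal variant">
##INFO=<ID=VTYPE,Number=1,Type=String,Description="SNP or InDel">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths for ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
"""


def write_truth_vcf(table: pd.DataFrame, spec: GenomeSpec, path: str | Path) -> Path:
    """Write the bulk-variant table as a two-sample VCF (MUT_BULK, WT_BULK).

    Records are strictly sorted by (contig order, position); the causal
    record carries the INFO flag ``CAUSAL``.  The file round-trips through
    :func:`bsamap.scancore.read_bulk_vcf` losslessly.
    """
    path = Path(path)
    order = {name: i for i, name in enumerate(spec.names)}
    keys = list(zip(table.chrom.map(order), table.pos))
    if keys != sorted(keys):
        raise ValueError("table must be sorted by (contig order, position)")
    lines = [_VCF_HEADER]
    for name, length in spec.chromosomes:
        lines.append(f"##contig=<ID={name},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMUT_BULK\tWT_BULK\n")
    for row in table.itertuples():
        info = f"VTYPE={row.vtype}"
        if getattr(row, "is_causal", False):
            info = "CAUSAL;" + info
        mut = f"./.:{row.mut_ref_depth},{row.mut_alt_depth}:{row.mut_ref_depth + row.mut_alt_depth}"
        wt = f"./.:{row.wt_ref_depth},{row.wt_alt_depth}:{row.wt_ref_depth + row.wt_alt_depth}"
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT:AD:DP\t{mut}\t{wt}\n"
        )
    path.write_text("".join(lines))
    return path


def write_truth_table(truth: TruthSet, path: str | Path) -> Path:
    """Write the truth TSV: chrom, pos, ref, alt, type, is_causal, f2_genotype."""
    path = Path(path)
    df = truth.variants[["chrom", "pos", "ref", "alt", "vtype", "is_causal"]].copy()
    df = df.rename(columns={"vtype": "type"})
    df["f2_genotype"] = truth.f2_founder_genotypes[0]
    df.to_csv(path, sep="\t", index=False)
    return path


# -- demo reference and gene model (plumbing for the annotation stage) -------


def write_reference_fasta(
    spec: GenomeSpec,
    variants: pd.DataFrame,
    path: str | Path,
    gene: "dict | None" = None,
    line_width: int = 70,
) -> Path:
    """Write a random reference genome consistent with the variant table.

    Each variant's REF string is planted at its coordinates.  When ``gene``
    (from :func:`make_causal_gene`) is given, the gene's CDS is made
    translatable: an ATG start, a terminal stop, and no internal stop
    codons — internal stops are patched only at bases outside any variant
    footprint so REF alleles stay intact.
    """
    path = Path(path)
    rng = _rng(spec, 5)
    with open(path, "w") as fh:
        for name, length in spec.chromosomes:
            seq = rng.choice(_DNA, size=length)
            footprint = np.zeros(length + 1, dtype=bool)
            for row in variants[variants.chrom == name].itertuples():
                ref = row.ref
                seq[row.pos - 1 : row.pos - 1 + len(ref)] = list(ref)
                footprint[row.pos - 1 : row.pos - 1 + len(ref)] = True
            if gene is not None and gene["chrom"] == name:
                _patch_cds(seq, footprint, gene)
            fh.write(f">{name}\n")
            s = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(s[i : i + line_width] + "\n")
    return path


def _patch_cds(seq: np.ndarray, footprint: np.ndarray, gene: dict) -> None:
    """Force a clean reading frame on the plus-strand demo gene in place."""
    start, end = gene["cds_start"] - 1, gene["cds_end"]  # 0-based half-open
    if not footprint[start : start + 3].any():
        seq[start : start + 3] = list("ATG")
    for c in range(start + 3, end - 3, 3):
        codon = "".join(seq[c : c + 3])
        if codon in ("TAA", "TAG", "TGA"):
            # patch one free base to break the stop
            for off in (2, 1, 0):
                if not footprint[c + off]:
                    seq[c + off] = "C"
                    break
    if not footprint[end - 3 : end].any():
        seq[end - 3 : end] = list("TGA")


def make_causal_gene(design: CrossDesign, cds_half_span: int = 600) -> dict:
    """A single-exon plus-strand gene model bracketing the causal variant.

    The CDS is anchored so the causal position sits mid-CDS in frame; the
    returned dict feeds :func:`write_reference_fasta` and the GFF3 writer.
    """
    if design.causal is None:
        raise ValueError("design has no causal variant")
    chrom, pos, _ = design.causal
    cds_start = pos - cds_half_span
    cds_start -= (pos - cds_start) % 3  # keep causal in frame with the CDS
    cds_end = pos + cds_half_span
    cds_end += 3 - (cds_end - cds_start + 1) % 3 if (cds_end - cds_start + 1) % 3 else 0
    return {
        "gene_id": "geneC",
        "chrom": chrom,
        "strand": "+",
        "gene_start": cds_start - 150,
        "gene_end": cds_end + 150,
        "cds_start": cds_start,
        "cds_end": cds_end,
    }


def write_gene_gff3(gene: dict, path: str | Path) -> Path:
    """Write the demo gene as a minimal GFF3 (gene/mRNA/exon/CDS)."""
    path = Path(path)
    g = gene
    lines = [
        "##gff-version 3\n",
        f"{g['chrom']}\tbsamap\tgene\t{g['gene_start']}\t{g['gene_end']}\t.\t{g['strand']}\t.\tID={g['gene_id']}\n",
        f"{g['chrom']}\tbsamap\tmRNA\t{g['gene_start']}\t{g['gene_end']}\t.\t{g['strand']}\t.\tID={g['gene_id']}.1;Parent={g['gene_id']}\n",
        f"{g['chrom']}\tbsamap\texon\t{g['gene_start']}\t{g['gene_end']}\t.\t{g['strand']}\t.\tID={g['gene_id']}.1.exon1;Parent={g['gene_id']}.1\n",
        f"{g['chrom']}\tbsamap\tCDS\t{g['cds_start']}\t{g['cds_end']}\t.\t{g['strand']}\t0\tID={g['gene_id']}.1.cds1;Parent={g['gene_id']}.1\n",
    ]
    path.write_text("".join(lines))
    return path
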