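"""Minimal coding-effect annotation for candidate variants.

Classifies a variant against a single-transcript gene model into the
consequence classes that matter for forward-genetics candidate triage:
frameshift, stop gain/loss, missense, synonymous, in-frame insertion or
deletion, and the noncoding classes (UTR, intronic, intergenic).  The edited
CDS is re-translated with the standard nuclear genetic code and, for
truncating changes, the residue index of the first novel stop codon is
reported.

Coordinates follow GFF3/VCF conventions: 1-based inclusive intervals and
1-based variant positions.  Variants are normalised (common suffix then
prefix stripped, left-aligned minimal representation) before any overlap
test, so VCF-style anchored indels and minimal indels classify identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import gffutils
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "VariantEffect",
    "read_gff3",
    "extract_cds",
    "apply_variant",
    "classify_effect",
    "annotate_variant",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon and CDS structure on a chromosome.

    Intervals are 1-based inclusive, stored in ascending genomic order;
    ``phase`` is the phase of the first CDS segment in transcription order
    (bases to trim before the first complete codon).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        cds = tuple(sorted(tuple(iv) for iv in self.cds))
        exons = tuple(sorted(tuple(iv) for iv in self.exons))
        for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
            if s2 <= e1:
                raise ValueError("CDS intervals must be non-overlapping")
        for s, e in cds:
            if not any(xs <= s and e <= xe for xs, xe in exons):
                raise ValueError(f"CDS segment ({s},{e}) not contained in any exon")
        total = sum(e - s + 1 for s, e in cds) - self.phase
        if total < 3:
            raise ValueError("total CDS length after phase trim must be >= 3")
        object.__setattr__(self, "cds", cds)
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class VariantEffect:
    """Consequence call for one variant against one gene model."""

    gene_id: str | None
    category: str  # intergenic|intronic|utr|synonymous|missense|stop_gained|
    #               stop_lost|inframe_deletion|inframe_insertion|frameshift|no_change
    protein_change: str = ""
    truncated_at: int | None = None  # 1-based residue index of first novel stop


# ---------------------------------------------------------------------------
# GFF3 input


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Parse gene models from GFF3; one GeneModel per gene.

    When a gene has several mRNAs the one with the largest total CDS length
    is kept.  CDS segments must lie within the declared gene span.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best: GeneModel | None = None
        best_len = -1
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            exon_feats = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
            if not cds_feats:
                continue
            for f in cds_feats:
                if f.start < gene.start or f.end > gene.end:
                    raise ValueError(
                        f"CDS {f.start}-{f.end} outside gene span of {gene.id}"
                    )
            if not exon_feats:  # tolerate exon-less annotations
                exon_feats = cds_feats
            first = cds_feats[0] if gene.strand == "+" else cds_feats[-1]
            phase = int(first.frame) if first.frame not in (None, ".") else 0
            model = GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=tuple((f.start, f.end) for f in exon_feats),
                cds=tuple((f.start, f.end) for f in cds_feats),
                phase=phase,
            )
            total = sum(e - s + 1 for s, e in model.cds)
            if total > best_len:
                best, best_len = model, total
        if best is not None:
            models[best.gene_id] = best
    return models


# ---------------------------------------------------------------------------
# sequence extraction and editing


def _chrom_seq(genome, chromosome: str) -> str:
    seq = genome[chromosome]
    return str(seq[:]) if hasattr(seq, "__getitem__") and not isinstance(seq, str) else str(seq)


def extract_cds(model: GeneModel, genome: Mapping[str, object]) -> str:
    """Spliced CDS in transcription order (revcomped for −), phase-trimmed."""
    chrom = _chrom_seq(genome, model.chromosome)
    for s, e in model.cds:
        if e > len(chrom):
            raise ValueError(f"CDS interval ({s},{e}) exceeds chromosome length {len(chrom)}")
    plus = "".join(chrom[s - 1 : e] for s, e in model.cds)
    seq = plus if model.strand == "+" else str(Seq(plus).reverse_complement())
    return seq[model.phase :]


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-aligned representation: strip common suffix then prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) > 1 and len(alt) >= 1 and ref[0] == alt[0] and len(alt) == 1:
        pass  # anchored deletion: keep anchor, handled downstream
    return pos, ref, alt


def apply_variant(
    model: GeneModel,
    genome: Mapping[str, object],
    variant: tuple[str, int, str, str],
) -> tuple[str | None, str | None]:
    """Edit the CDS with one variant.

    Returns ``(mut_cds, None)`` when the variant overlaps the CDS, else
    ``(None, category)`` with category utr / intronic / intergenic.  The
    variant's REF allele must match the genome at its coordinates.
    """
    chrom_name, pos, ref, alt = variant
    if chrom_name != model.chromosome:
        return None, "intergenic"
    chrom = _chrom_seq(genome, chrom_name)
    if chrom[pos - 1 : pos - 1 + len(ref)].upper() != ref.upper():
        raise ValueError(
            f"REF allele {ref!r} does not match genome at {chrom_name}:{pos} "
            f"(found {chrom[pos - 1 : pos - 1 + len(ref)]!r})"
        )
    pos, ref, alt = normalize_variant(pos, ref, alt)
    # drop a shared anchor base from indels so the affected interval is exact
    if len(ref) != len(alt) and ref[0] == alt[0]:
        pos, ref, alt = pos + 1, ref[1:], alt[1:]

    if ref:
        affected = range(pos, pos + len(ref))  # substituted or deleted bases
    else:
        affected = range(pos, pos)  # pure insertion: junction before `pos`

    cds_positions: list[int] = []
    for s, e in model.cds:
        cds_positions.extend(range(s, e + 1))
    cds_set = set(cds_positions)

    overlaps_cds = any(p in cds_set for p in affected) if ref else _junction_in_cds(model, pos)
    if not overlaps_cds:
        span = model.span
        in_gene = span[0] <= pos <= span[1]
        in_exon = any(s <= pos <= e for s, e in model.exons)
        if not in_gene:
            return None, "intergenic"
        return (None, "utr") if in_exon else (None, "intronic")

    # edit in plus orientation on the spliced CDS
    plus = list("".join(_chrom_seq(genome, chrom_name)[s - 1 : e] for s, e in model.cds))
    index_of = {p: i for i, p in enumerate(cds_positions)}
    if ref:  # deletion / substitution of the CDS-overlapping part
        del_idx = sorted(index_of[p] for p in affected if p in cds_set)
        insert_at = del_idx[0]
        for i in reversed(del_idx):
            del plus[i]
        if alt:
            plus[insert_at:insert_at] = list(alt)
    else:  # pure insertion at a junction inside the CDS
        insert_at = index_of[pos]
        plus[insert_at:insert_at] = list(alt)
    mut_plus = "".join(plus)
    mut = mut_plus if model.strand == "+" else str(Seq(mut_plus).reverse_complement())
    return mut[model.phase :], None


def _junction_in_cds(model: GeneModel, pos: int) -> bool:
    """Insertion between pos-1 and pos falls inside the CDS when both flanks do."""
    cds_set = set()
    for s, e in model.cds:
        cds_set.update(range(s, e + 1))
    return pos in cds_set and (pos - 1) in cds_set


# ---------------------------------------------------------------------------
# classification


def _translate_to_stop(cds: str) -> tuple[str, int | None]:
    """Protein up to (excluding) the first stop; codon index of that stop."""
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3].upper()
        if codon in _STOPS:
            return "".join(protein), i // 3 + 1
        protein.append(str(Seq(codon).translate()))
    return "".join(protein), None


def classify_effect(ref_cds: str, mut_cds: str, gene_id: str | None = None) -> VariantEffect:
    """Compare reference and mutant CDS translations.

    The reference CDS must translate without an internal stop (a premature
    stop in the annotation is an error).  Frameshifts (length change not
    divisible by 3) scan the shifted frame to the first stop and report its
    residue index; in-frame changes classify as stop_gained / stop_lost /
    synonymous / missense / inframe_deletion / inframe_insertion.
    """
    ref_p, ref_stop = _translate_to_stop(ref_cds)
    n_ref_codons = len(ref_cds) // 3
    if ref_stop is not None and ref_stop < n_ref_codons:
        raise ValueError(f"reference CDS has an internal stop at codon {ref_stop}")
    if ref_cds == mut_cds:
        return VariantEffect(gene_id, "no_change", "p.=")

    mut_p, mut_stop = _translate_to_stop(mut_cds)
    delta = len(mut_cds) - len(ref_cds)

    if delta % 3 != 0:
        return VariantEffect(
            gene_id,
            "frameshift",
            f"fs*{mut_stop}" if mut_stop is not None else "fs(no stop)",
            truncated_at=mut_stop,
        )

    expected_len = len(ref_p) + delta // 3
    if mut_stop is not None and len(mut_p) < expected_len:
        return VariantEffect(
            gene_id, "stop_gained", f"p.{_aa_at(ref_p, mut_stop)}{mut_stop}*", truncated_at=mut_stop
        )
    if ref_stop is not None and mut_stop is None:
        return VariantEffect(gene_id, "stop_lost", "p.*?ext")
    if mut_p == ref_p:
        return VariantEffect(gene_id, "synonymous", "p.=")
    if delta < 0:
        return VariantEffect(gene_id, "inframe_deletion", _indel_change(ref_p, mut_p))
    if delta > 0:
        return VariantEffect(gene_id, "inframe_insertion", _indel_change(ref_p, mut_p))
    i = next(k for k, (a, b) in enumerate(zip(ref_p, mut_p)) if a != b)
    return VariantEffect(gene_id, "missense", f"p.{ref_p[i]}{i + 1}{mut_p[i]}")


def _aa_at(protein: str, idx: int) -> str:
    return protein[idx - 1] if 0 < idx <= len(protein) else "?"


def _indel_change(ref_p: str, mut_p: str) -> str:
    """Describe an in-frame protein-length change, e.g. 'p.P5del'."""
    i = 0
    while i < min(len(ref_p), len(mut_p)) and ref_p[i] == mut_p[i]:
        i += 1
    if len(mut_p) < len(ref_p):
        n = len(ref_p) - len(mut_p)
        removed = ref_p[i : i + n]
        return f"p.{removed}{i + 1}del"
    n = len(mut_p) - len(ref_p)
    added = mut_p[i : i + n]
    return f"p.{i}_{i + 1}ins{added}"


def annotate_variant(
    model: GeneModel,
    genome: Mapping[str, object],
    variant: tuple[str, int, str, str],
    ref_cds: str | None = None,
) -> VariantEffect:
    """Convenience: apply a variant to a gene model and classify the result."""
    mut_cds, category = apply_variant(model, genome, variant)
    if category is not None:
        return VariantEffect(model.gene_id if category != "intergenic" else None, category)
    if ref_cds is None:
        ref_cds = extract_cds(model, genome)
    return classify_effect(ref_cds, mut_cds, gene_id=model.gene_id)
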