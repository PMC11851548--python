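"""Shared fixtures: toy gene models and VCF builders.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write.
"""

from __future__ import annotations

import textwrap

import pytest
from Bio.Seq import Seq

from bsamap.effector import GeneModel

PAD = "ACGTACGTAC"  # 10 bp of flanking sequence

#: frameshift fixture: deleting the C at CDS base 4 turns codon 2 into TAA
CDS_FRAMESHIFT = "ATGCTAACCTTTTAA"  # M L T F *

#: in-frame fixture: deleting TCC (CDS bases 9-11) removes one proline
CDS_PROLINE = "ATGGAACCTCCATTTTAA"  # M E P P F *


@pytest.fixture
def gene_plus():
    """Single-exon + strand gene with the proline-deletion CDS.

    Returns (model, genome dict); CDS occupies genomic 11..28 (1-based).
    """
    seq = PAD + CDS_PROLINE + PAD
    model = GeneModel(
        gene_id="toyP",
        chromosome="chrT",
        strand="+",
        exons=((6, len(seq) - 5),),  # 5 bp UTR on each side of the CDS
        cds=((11, 10 + len(CDS_PROLINE)),),
    )
    return model, {"chrT": seq}


@pytest.fixture
def gene_frameshift():
    """Single-exon + strand gene with the frameshift CDS (11..25)."""
    seq = PAD + CDS_FRAMESHIFT + PAD
    model = GeneModel(
        gene_id="toyF",
        chromosome="chrT",
        strand="+",
        exons=((6, len(seq) - 5),),
        cds=((11, 10 + len(CDS_FRAMESHIFT)),),
    )
    return model, {"chrT": seq}


@pytest.fixture
def gene_minus(gene_plus):
    """The proline gene mirrored onto the - strand of the revcomp chromosome."""
    model, genome = gene_plus
    seq = genome["chrT"]
    rc = str(Seq(seq).reverse_complement())
    L = len(seq)

    def mirror(iv):
        s, e = iv
        return L - e + 1, L - s + 1

    m = GeneModel(
        gene_id="toyP_rc",
        chromosome="chrT",
        strand="-",
        exons=tuple(mirror(iv) for iv in model.exons),
        cds=tuple(mirror(iv) for iv in model.cds),
    )
    return m, {"chrT": rc}


@pytest.fixture
def gene_split():
    """The proline CDS split over two exons by a 12 bp intron after base 9."""
    intron = "GTAAGTTTTCAG"
    seq = PAD + CDS_PROLINE[:9] + intron + CDS_PROLINE[9:] + PAD
    cds1 = (11, 19)  # first 9 CDS bases
    cds2 = (20 + len(intron), 19 + len(intron) + len(CDS_PROLINE) - 9)
    model = GeneModel(
        gene_id="toyS",
        chromosome="chrT",
        strand="+",
        exons=((6, cds1[1]), (cds2[0], len(seq) - 5)),
        cds=(cds1, cds2),
    )
    return model, {"chrT": seq}, intron


def write_vcf(path, rows, contigs=(("chr1", 1_000_000),)):
    """Write a minimal two-bulk VCF; rows are dicts with chrom/pos/ref/alt
    and the four depths."""
    header = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##INFO=<ID=CAUSAL,Number=0,Type=Flag,Description="x">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
        ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
        """
    )
    lines = [header]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMUT_BULK\tWT_BULK\n")
    for r in rows:
        mut = f"./.:{r['mut_ref']},{r['mut_alt']}:{r['mut_ref'] + r['mut_alt']}"
        wt = f"./.:{r['wt_ref']},{r['wt_alt']}:{r['wt_ref'] + r['wt_alt']}"
        info = r.get("info", ".")
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t{info}\tGT:AD:DP\t{mut}\t{wt}\n"
        )
    path.write_text("".join(lines))
    return path
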