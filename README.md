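# bsamap

Bulked-segregant mapping of EMS-induced mutants: a simulator of the mapping
cross, a SNP-index/ΔIndex genome scan with sliding-window peak calling, a
coding-effect annotator for candidate triage, and the accompanying
segregation and expression statistics.

## The problem

Forward genetics in selfing crops such as rice often starts from a chemically
mutagenised (EMS) line with an interesting recessive phenotype — here, a
late-heading mutant.  To map the causal mutation, the mutant is crossed to
its progenitor, the F1 is selfed, and an F2 plant heterozygous at the causal
locus founds an F3 family that segregates 3:1 (normal : mutant).  Two bulks
of ~30 plants — one per phenotype class — are pooled and sequenced at ~30×
(the MutMap/MutMap+ family of designs).

At each variant site the **SNP index** of a bulk is the fraction of reads
carrying the mutant (alternate) allele,

```
index = alt_depth / (alt_depth + ref_depth)
ΔIndex = index(mutant bulk) − index(wild-type bulk)
```

Around the causal locus the mutant bulk is fixed for the mutant allele
(index → 1) while the wild-type bulk — drawn from a segregating family in
which normal plants are 1/3 homozygous wild type and 2/3 heterozygous —
sits near 1/3, so linked variants have E[ΔIndex] = 2/3 and unlinked ones
E[ΔIndex] = 0.  The scan averages ΔIndex in 0.5 Mb sliding windows (10 kb
step), thresholds at the mean + 3·SD of all per-variant ΔIndex values, merges
supra-threshold windows into peak regions, and ranks region variants with
ΔIndex > 0.22 by coding consequence (frameshift/stop/missense/in-frame indel
above silent or noncoding).

Because no real resequencing data ship with this package, a forward
simulator (`bsamap.simpop`) generates truth-annotated populations — EMS
variant spectra, Haldane meiosis, recessive phenotyping, bulk construction,
Poisson/binomial read sampling — so every downstream stage is testable end
to end.

## Worked example

The numbered drivers under `analysis/` run one deterministic demo experiment
(5 × 5 Mb chromosomes, 500 EMS variants, a 1-bp causal deletion on
chromosome 3, bulks of 30 at 30×):

```
$ python analysis/01_simulate_population.py
simulated F3 family: 155 normal : 45 late (expected 150:50 under 3:1)
chi2 = 0.6667, df = 1, p = 0.4142 -> consistent with 3:1

$ python analysis/02_genome_scan.py
threshold (mean + 3*SD of per-variant dIndex): 0.5358
peak chr3:2020000-3230000 (72 windows, max window dIndex 0.678)  <- contains the causal variant
planted causal variant: chr3:2500000 (AA->A)

$ python analysis/03_annotate_candidates.py
25 candidate variant(s) with dIndex > 0.22 in the peak region
top-ranked: chr3:2500000 AA->A [frameshift], dIndex 0.690 -> the planted causal variant
```

The family segregates 3:1, the scan flags a single ~1.2 Mb region on
chromosome 3 containing the planted mutation, and candidate triage puts the
causal 1-bp deletion first because it is the only protein-changing variant
(a frameshift with premature termination) above the ΔIndex cutoff.
`analysis/04_…` reproduces the published-style segregation/qPCR/trait/DEG
statistics and `analysis/05_…` runs replicated positive and negative
controls of the scan.

The same stages are scriptable from a shell:

```
bsa run --config cfg.yaml --out out/          # simulate -> scan -> annotate -> report
bsa scan --vcf bulks.vcf --fai ref.fa.fai --out out/
bsa stats segregation --counts 156,44 --ratio 3,1 --df 2
```

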