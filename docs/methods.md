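# Methods

## Population model

The simulator reproduces the standard recessive-mutant mapping design in a
selfing crop:

1. **EMS variants.** `ems_variant_count` variant sites are placed uniformly
   at random (without replacement, chromosomes weighted by length).  SNVs
   follow the canonical EMS spectrum — G:C→A:T transitions — because EMS
   alkylates guanine; InDels (fraction `indel_fraction`, default 0.1) are
   1–12 bp with a VCF-style left anchor base.  All sites are biallelic.  The
   designated causal variant is forced into the set at its stated
   coordinates (default: a 1-bp frameshift deletion mid-chromosome 3).
2. **Meiosis.** Gametes are produced by a Poisson crossover process without
   interference (Haldane): the expected crossover count per chromosome is
   `length_Mb × rate_cM_per_Mb / 100`, crossover positions uniform.  The F1
   is heterozygous at every EMS site (mutant × progenitor cross).
3. **Family structure.** One F2 offspring of the selfed F1 founds the F3
   family; it is resampled until heterozygous at the causal locus, mirroring
   how segregating F3 families are selected in practice.  `f3_family_size`
   (default 200) F3 plants are produced by selfing the founder.  Multiple
   pooled families are supported (`n_families`), single-family is default.
4. **Phenotype.** Strictly recessive and fully penetrant: a plant is mutant
   ("late") iff it carries two mutant alleles at the causal site.  In
   causal-free null designs the phenotype is instead drawn independently
   with P(late) = 0.25, so bulks can still be formed while no variant is
   associated with the trait — the intended negative control.
5. **Bulks and reads.** `bulk_size` (default 30) plants are drawn without
   replacement from each phenotype class.  Per site and bulk, total depth is
   Poisson(`mean_depth`, default 30); each read carries the alternate allele
   with probability `f(1−e) + (1−f)e`, where `f` is the bulk allele
   frequency (mean member dosage / 2) and `e` the per-read error
   (default 0.002, Illumina-typical).

Under this model the causal site's expected mutant-bulk index is 1 − e and
the wild-type-bulk index is 1/3 (normal plants of a 3:1 family are 1/3
homozygous wild type, 2/3 heterozygous), so E[ΔIndex] ≈ 2/3 — the quantity
the replicated benchmark checks.

## Scan statistic

* **Index.** `alt/(alt+ref)` per bulk; undefined (NaN) at zero depth.
  ΔIndex is mutant-bulk minus wild-type-bulk index; peak calling uses the
  upper tail only (the recessive causal allele is enriched in the mutant
  bulk); the mirrored lower-tail mode is available behind a flag.
* **Filters.** Variants are dropped when either bulk's total depth is below
  `min_depth` (default 20 reads) or an index is undefined.  An optional
  progenitor-heterozygosity proxy drops variants whose wild-type-bulk index
  falls in a configurable band (default [0.35, 0.65]); it is off by default
  because simulated populations contain no parental heterozygosity.
* **Windows.** 0-based half-open windows anchored at multiples of `step`
  (default 10 kb), width `window` (default 0.5 Mb).  Full windows advance
  while `start + window ≤ L`; at most one final window is truncated at the
  chromosome end.  A variant with 1-based position p belongs to [s, e) iff
  s < p ≤ e.  The window mean is the arithmetic mean of member ΔIndex
  values, NaN when empty (empty windows can never exceed a threshold).
* **Threshold.** mean ± k·SD (default k = 3) over *per-variant* ΔIndex
  values of the scanned variant type, not over window means; the SD is the
  sample SD (n−1 denominator, matching R's `sd`).  Fewer than two defined
  ΔIndex values is an error.
* **Peaks.** Maximal runs of consecutive windows with defined mean above
  the upper threshold are merged; because windows overlap (window ≫ step),
  runs whose spans overlap are merged again so reported regions are
  non-overlapping.  Regions spanning fewer than `min_windows` windows
  (default 1) are discarded.
* **Triage.** Region variants with ΔIndex > `delta_cutoff` (default 0.22)
  are joined to their coding consequence and ranked: protein-changing
  consequences (stop gain/loss, frameshift, missense, in-frame indels)
  first, then descending ΔIndex, then position.

## Effect annotation

Gene models come from GFF3 (gene/mRNA/exon/CDS); when a gene has several
mRNAs the one with the largest total CDS is used.  Variants are normalised
to a minimal left-aligned representation before overlap tests, so anchored
VCF indels and minimal indels classify identically.  The edited CDS is
re-translated with the standard nuclear code: frameshifts (length change
not divisible by 3) scan the shifted frame and report the residue index of
the first novel stop; in-frame changes classify as synonymous, missense,
stop_gained, stop_lost, or in-frame insertion/deletion.  A reference CDS
with an internal stop is rejected as a bad annotation, and a variant whose
REF allele disagrees with the genome raises immediately (this guards
coordinate bugs).  Identical input sequences return the category
`no_change`.  Splice-site and regulatory annotation are out of scope;
indels spanning a CDS boundary classify by the length change of their
CDS-overlapping portion.

## Statistics

* Segregation: Pearson chi-square goodness of fit without continuity
  correction (the uncorrected statistic reproduces the worked values
  exactly); df defaults to classes − 1 but is an explicit parameter because
  published reports sometimes use other conventions, and the CLI prints
  both.
* Co-segregation: discordance counting under the recessive model.
* qPCR: fold change 2^−ΔΔCt from target/reference Ct pairs of a sample and
  a calibrator.
* Trait contrast: Student's pooled-variance two-sample t; zero-variance
  degenerate inputs return t = 0, p = 1 (equal means) or p = 0 (unequal).
* DEG screen: strict thresholds (log2FC > 0.5, padj < 0.05 by default) on an
  existing differential-expression results table; the differential test
  itself is upstream of this package.

## The miniature benchmark genome

The replicated benchmarks run on 5 × 5 Mb chromosomes with 500 EMS
variants — a ~15× physical scale-down of a rice-sized genome.  Genetic map
density cannot be scaled naively: at a rice-like 4 cM/Mb an entire 5 Mb
chromosome (20 % of the genome) would co-segregate with the causal locus,
a geometry the real experiment never has, and the mean + 3·SD threshold
would exceed the Mendelian ceiling of 2/3.  The density is therefore chosen
from the geometry of the design: the founder's heterozygous tract around
the causal locus, roughly `chrom_bp / (2·crossovers + 1)`, must stay small
against the genome (else the threshold inflates) yet wide against the
0.5 Mb window (else the peak dilutes).  Two crossovers per gamete per
chromosome (200 cM per 5 Mb chromosome, i.e. 40 cM/Mb) give a ~1 Mb tract,
~4 % of the genome, with the window comfortably inside — both constraints
met.  For user-supplied real-scale data the default map stays 4 cM/Mb.
The benchmark scans SNVs and InDels together: with only 50 simulated
InDels an InDel-only scan would average ~1 variant per window.

## What the simulator does and does not emulate

It emulates the study design — the cross, 3:1 segregation, phenotype bulks,
depth and error of bulk sequencing — and therefore supports end-to-end
validation of the scan's logic, determinism and Mendelian expectations.  It
does **not** emulate: cultivar background variants from aligning against a
different reference (real scans contain orders of magnitude more
uninformative delta≈0 sites, which shrink the SD and hence the threshold),
variant-caller artifacts and genotype-call-based filtering, EMS mutation
clustering, crossover interference, gene conversion, or incomplete
penetrance.  Passing benchmarks show the statistic behaves correctly under
the idealised design, not that the pipeline is robust to real-data artifact
modes.

## Known limitations

* **Threshold self-inflation at miniature scale.**  Conditioning the founder
  on heterozygosity at the causal locus makes the linked tract 4–8 % of the
  25 Mb benchmark genome.  Those high-ΔIndex variants inflate the SD of the
  very distribution the threshold is computed from, so mean + 3·SD
  (typically 0.5–0.7 here) sits close to the attainable peak height
  (≈ 0.6–0.65), and in roughly one run in ten no window clears it.  The
  replicated recovery control accordingly plateaus near 90 % at these
  conditions; on a full-size genome the linked fraction is < 1 % and the
  same rule thresholds far below the peak.  The `05_scan_benchmarks` driver
  and the acceptance script report the measured rates.
* Single-transcript annotation, standard genetic code only.
* The read model is site-independent (no alignment-level correlation,
  mapping bias or duplicate structure).
* The demo reference FASTA and gene model written by the pipeline are
  synthetic constructions consistent with the simulated variants, intended
  only to exercise the annotation stage.
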