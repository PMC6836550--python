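# cytowgs

Short-read whole-genome sequencing (WGS) can replace chromosomal
microarray as a first-line genetic test for intellectual disability and
rare disease — if the downstream analyses that clinical cytogenetics
relies on are available for WGS call sets.  `cytowgs` implements that
post-calling toolchain as a tested Python library with a thin CLI:

* **SV call-set handling** — merging complementary callers (read-depth vs
  discordant-pair), building allele-frequency databases from cohorts, and
  the clinical filter cascade: size (intergenic > 10 kb, intragenic >
  2 kb), quality (≥ 6 read pairs for pair-only calls, ≥ 5 kb for
  depth-only calls), frequency (population AF ≤ 0.5 %, internal AF < 1 %),
  decoy-contig removal, plus a gene-panel *rescue* lane with no size
  cutoff.
* **Array emulation** — exporting SV calls as synthetic probe log2 ratios
  (a CGH-style XML dialect), calling CNVs with the
  three-consecutive-aberrant-probe rule (−0.65 / +0.35 cutoffs), MLPA
  ratio interpretation (< 0.75 deletion, > 1.3 duplication), and a
  direction-matched WGS-vs-array overlap report.
* **Derivative chromosomes** — clustering SVs into rearrangements,
  walking a breakend graph into ordered signed segment lists (rings
  included), classifying topology (DEL-INV-DEL, tandem vs insertional
  duplication, reciprocal/unbalanced translocation, …) and decomposing
  breakpoint junctions into microhomology, non-templated and templated
  insertions to suggest a formation mechanism (NHEJ-like,
  replicative-like, NAHR-like).
* **ROH / UPD** — windowed homozygous-SNV fractions (10-kb windows), a
  run-of-homozygosity caller, and uniparental-disomy typing from trio (or
  single-parent) genotypes.
* **STR genotyping** — exact repeat counts from tract-spanning reads and
  an in-repeat-read estimator for expansions beyond the read length, with
  a bundled 17-gene catalog (*ATXN7*, *HTT*, *FMR1*, …).
* **Mosaic aneuploidy** — chromosome coverage ratios over a robust
  autosomal baseline; a mosaic gain fraction inverts as `f = 2(r − 1)`.
* **Synthetic data** — seeded generators for every input above (caller
  outputs with caller-specific blind spots, probe series, SNV/trio sites,
  STR reads, depth bins), each returning its planted truth.

All coordinates follow the convention of clinical CNV tables: a region
`chrN:start-end` has length `end − start`.

## Worked example

Genotyping the *ATXN7* CAG repeat from simulated 151-bp reads at 30×
(`examples/04_str_genotyping.py`):

```
locus: ATXN7 chr3:63898361-63898391 (CAG)n, pathogenic >= 37 units
planted 10/46: called 10/46 (spanning-exact, 0 in-repeat reads, pathogenic=True)
planted 10/233: called 10/248 (inrepeat-estimated, 59 in-repeat reads, pathogenic=True)
```

The 46-unit allele (138-bp tract) still fits inside a read, so it is
counted exactly from reads that span the whole tract.  The 233-unit
allele (699 bp) exceeds the read length; the 59 reads consisting purely
of repeat motif invert the read-sampling model to an estimated 248 units
(~6 % high here; accuracy is about ±10 % at this coverage).  Both calls
exceed the catalog's 37-unit threshold and are flagged.

The other `examples/*.py` scripts each demonstrate one capability end to
end — the filter cascade with panel rescue, array emulation and platform
comparison, derivative-chromosome reconstruction (including a ring
chromosome 18), isodisomy detection on chromosome 15, and mosaic
trisomy 9 quantification — printing both the computed numbers and what
they mean.

A thin CLI mirrors the library:

```sh
cytowgs simulate --what depth --seed 3 --out bins.tsv
cytowgs mosaic --bins bins.tsv
cytowgs convert --vcf calls.vcf --cgh calls.cgh --spacing 18000
```

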