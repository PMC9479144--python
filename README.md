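# mitescan

Detection of **mPing** insertion sites from anchored-amplicon (transposon
display) sequencing, by two independent methods that are then reconciled,
annotated by genic context, and joined against a differential-expression
table.

mPing is a 430-bp rice MITE (miniature inverted-repeat transposable
element) of the Tourist family, with 15-bp terminal inverted repeats (TIRs)
and a 3-bp target-site duplication (TSD). In some rice strains it is
actively transposing, so sister lines accumulate different insertion sets;
locating those insertions genome-wide, and asking whether they sit in or
near genes — in particular near differentially expressed genes (DEGs) — is
the analysis this package implements. The input is a library of paired
reads in which read 1 starts at an mPing terminus and runs into flanking
host genome.

## The two detectors

**Reference-free (clustering).** Read 1 is quality-trimmed (Phred ≥ 30),
anchor-verified, stripped to pure flank, and trimmed to a fixed length.
Distinct flank sequences with ≥ 10 identical copies are dereplicated and
clustered greedily around abundance-ranked centroids at ≥ 90% ungapped
identity; each cluster is one candidate insertion site. A line carries the
insertion when the cluster's reads are ≥ 0.01% of that line's total —
giving a lines × sites presence/absence genotype matrix without touching a
reference genome.

**Reference-based (alignment).** Flanks are placed uniquely on the
reference; the junction-proximal start of every alignment is collected, and
starts within a 500-bp window are grouped into a locus. A locus with ≥ 50
supporting reads is a called site; smaller loci are kept as sub-threshold
candidates.

**Reconciliation.** Per line, cluster sites matched to an alignment site
(within 100 bp) are *common*; unmatched cluster sites matched to a
sub-threshold locus (≥ 1 aligned read) are *rescued* — independently
supported by both routes, they are considered actually present. The final
set is common ∪ rescued. Final sets are compared across lines (Venn
partition), classified as inside / near (≤ 3 kb) / intergenic against the
gene models with a χ² test against the genome's base-pair baseline, and
joined with a DEG table (sites inside or within 3 kb of a DEG).

Because real MiSeq data cannot ship with the package, a first-class
simulator generates the complete study: a toy genome with gene models,
planted elements with TIR/TSD mechanics and known truth, the anchored
library (Poisson coverage, 400–600-bp fragments, base-call errors), and a
DEG table with designated up-/down-regulated genes.

## Worked example

```python
from mitescan import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(seed=1), "run_demo")
```

or, from the shell, `mitescan run-all --outdir run_demo --seed 1`.
This simulates three lines (one control `C1`, two `HP` lines) with 30
planted insertions each (18 shared, 12 line-specific) and runs every stage.
`run_demo/table1.tsv` then reads:

```
line_id  n_cluster  n_align  n_common  pct_common  n_rescued  n_total
     C1         30       30        30       100.0          0       30
    HP1         30       30        30       100.0          0       30
    HP2         30       30        30       100.0          0       30
```

Both detectors found all 30 planted sites per line, every cluster site was
confirmed by alignment (100.0%), and nothing needed rescuing — at 100×
coverage with 0.1% base errors the two methods agree perfectly. The genic
distribution (`table2.tsv`) and the cross-line comparison (`venn.tsv`):

```
line_id  n_inside  pct_inside  n_near  pct_near  n_intergenic  pct_intergenic  total
     C1         3        10.0      19      63.3             8            26.7     30
...
     lines  n_sites
        C1       12
       HP1       12
       HP2       12
C1+HP1+HP2       18
```

i.e. the called sites reproduce the planted sharing structure exactly, and
skew toward near-gene placements relative to the genome baseline
(`baseline.tsv`: 27.7 / 32.0 / 40.3% inside/near/intergenic), which the χ²
preference test in `preference.tsv` quantifies.

Every stage reads and writes plain files in the run directory, so stages
can be rerun individually (`mitescan annotate --outdir run_demo ...`), and
`manifest.json` records all parameters plus a checksum of every output.

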