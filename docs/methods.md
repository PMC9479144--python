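# Methods

This note documents the models, parameter choices and numerical conventions
behind mitescan, and what the simulated validation does and does not show.

## Coordinates and formats

Positions are 1-based inclusive everywhere in the library; BED6 output is
0-based half-open, with single-base intervals marking junctions. FASTQ is
Phred+33. An insertion's *position* is the 1-based host base immediately 5'
of the planted element.

## Preprocessing

Quality trimming removes the 3' tail of a read using the partial-sum
algorithm popularized by cutadapt: scanning from the 3' end, the running
sum of `(cutoff − quality)` is maximized and the read is cut there; a read
whose trimmed length falls below `anchor + trim_len` is dropped. The
cutoff defaults to Phred 30. This operation is idempotent (trimming a
trimmed read is a no-op), which the property suite checks.

The anchor — the element's terminal 15-mer as it appears at the start of
read 1 — must match the read's 5' prefix within `anchor_mismatch`
substitutions (default 1). The remaining flank is truncated to `trim_len`
(default 100 bases): the published protocol trims "to a specific length"
without quantifying it, and 100 bases of a 150-bp read minus the 15-base
anchor keeps nearly every read while making flanks from one site
string-identical, which the dereplication step depends on. Only read 1
enters detection; read 2 (the adapter side) carries no junction
information in this design.

## Reference-free detector

Dereplication keeps distinct flank sequences whose total abundance across
lines is ≥ `min_abund` (default 10, boundary inclusive), preserving
per-line counts. Clustering is greedy centroid assignment: sequences in
descending total abundance (ties broken lexicographically, for
determinism) join the first cluster whose representative they match at
≥ `min_identity` (default 0.90) ungapped identity over the full trimmed
length, else found a new cluster. The representative is therefore always
the most abundant member. An external clustering aligner would do the same
job; an internal ungapped clusterer was chosen because the contract —
near-identical flanks co-cluster, distant flanks do not — is then exactly
testable against an all-pairs single-linkage oracle, with which greedy
assignment provably agrees when clusters are separated by more than twice
the mismatch tolerance (the oracle-equivalence suite generates exactly
such inputs).

Presence calling: line × cluster is 1 iff the cluster's reads for that
line are ≥ `frac_threshold` (default 10⁻⁴, i.e. 0.01%) of that line's
post-preprocessing flank total. The denominator is the flank count the
clusters were actually built from; the threshold is applied per
(line, cluster) cell. Raising the threshold can only switch calls 1→0
(monotonicity property).

## Reference-based detector

The internal mapper reports the placement of a flank that occurs exactly
once in the reference (both strands searched); reads occurring zero or
multiple times are dropped and counted. With `map_mismatch > 0` the best
placements within that edit distance are found instead (edlib infix
alignment), with equal-cost placements closer than half the flank length
collapsed to one locus. Pre-computed SAM is also accepted (primary mapped
records only; a SAM without `@SQ` header lines is a hard error).

The coordinate kept per alignment is the *junction-proximal* end: the
leftmost reference base for forward alignments, the rightmost for reverse.
Anchored flanks from the two element orientations then stack at (nearly)
the same coordinate, so the window scan treats both strands together in a
single left-to-right pass — equivalent to grouping strands separately and
merging within-window loci, but simpler and directly checkable against the
exhaustive oracle. The scan opens a locus at the first unassigned start,
absorbs every start within `window` (default 500) bases of the opening
start, sets the locus position to the modal start (tie → smallest), and
repeats. Every start belongs to exactly one locus; the result is invariant
to input order. Loci with ≥ `min_reads` (default 50, per line) supporting
reads are called sites; the rest are retained as sub-threshold loci for
the rescue step.

The phrase "reads within a window of each aligned read" is ambiguous when
every read defines its own window; the repeated-minimum greedy cover was
fixed as the deterministic interpretation and is verified against an
independently coded exhaustive cover on random inputs.

## Reconciliation

Cluster representatives are placed on the reference with the same
unique-placement rule. Per line, cluster sites are matched one-to-one to
alignment sites (same chromosome, within `tol` = 100 bases, nearest
first); matches are *common*. Remaining cluster sites matched to a
sub-threshold locus are *rescued*: the reference-free method supports
them independently, so ≥ 1 aligned read suffices. Cluster sites with no
aligned reads at all are excluded from the final set and reported — the
only rescue arithmetic consistent with the published per-line count
structure (clustering total = common + rescued + unconfirmed). The
tolerance of 100 bases is well under the 500-bp calling window, so
distinct loci cannot be conflated; it is configurable because the original
matching rule is not published.

Cross-line comparison pools final sites, chains sorted positions whose
consecutive gaps are ≤ `tol` (the 1-D transitive closure of pairwise
matching), takes the smallest position as class representative, and counts
every region of the Venn partition. The partition is symmetric in line
order and its cardinalities sum to the number of site classes.

## Annotation and preference

A site is *inside* if within any gene span (TSS-to-TES, UTRs included),
else *near* if within `near_kb` (default 3) kilobases of the nearest span
boundary — inclusive at exactly 3,000, anchored at the span boundary since
the original anchor is not published — else *intergenic*. Inside takes
precedence; nearest gene ties break to the smaller gene id. Subfeatures:
UTR5/UTR3 win over exon, a non-exonic inside position is intron,
upstream/downstream resolve by gene strand; distances are signed
(negative upstream).

The genome baseline is the base-pair fraction of the three categories:
merged gene spans; merged 3-kb extensions minus the spans (overlapping
flanks counted once); remainder. The three fractions partition the genome
and are checked against a brute-force per-base labeling oracle.

Insertional preference is a χ² goodness-of-fit of observed category counts
against expected = total × baseline fraction (df = 2), with standardized
residuals (O−E)/√E giving direction. The published analysis asserts
significance without naming a test; χ² goodness-of-fit is the standard
choice for a three-category occupancy comparison. Monte-Carlo draws from
the baseline confirm the test's size (≈ 5% rejections at α = 0.05).

## DEG join

The module consumes a DE results table (gene_id, log2fc, padj, direction;
differential-expression calling itself is out of scope). Significant rows
(padj ≤ 0.05 by default) are paired with every insertion site inside their
gene span or within 3 kb of it, reusing the annotation module's distance
convention. The summary reports distinct proximal DEGs and their
percentage of *all* DEGs (unresolvable gene ids are warned about, skipped
and counted, but stay in the denominator). The percentage is monotone
non-decreasing in `near_kb`.

## Synthetic data

The generator emulates the study conditions end to end:

- **Genome**: 2 chromosomes × 150 kb of uniform random sequence, 16
  non-overlapping genes of 4.0–6.6 kb with 1–3 exons, introns and both
  UTRs. These defaults put the base-pair baseline at roughly 28% inside /
  32% near / 40% intergenic — deliberately close to the rice genome's
  gene-space proportions, so preference tests run against a realistic
  null.
- **Element**: a random 430-mer with enforced 15-bp TIR structure (starts
  with the TIR, ends with its reverse complement). The real element can
  be supplied instead; the TSD is whatever 3-mer occupies the target site
  (Tourist-family convention), not a fixed motif.
- **Planting**: three lines (one control, two "HP"), 30 insertions per
  line of which 60% are shared by all three; categories drawn with
  weights 0.15/0.55/0.30 (inside/near/intergenic), roughly the skew
  observed for this element family. Sites are ≥ 800 bases apart and ≥ 700
  bases from chromosome ends so fragments stay in bounds and loci stay
  distinct; each copy inserts the element plus the duplicated 3-bp target
  site (+433 bases), is recorded with strand and category (classified by
  the same rules the annotation module applies), and excising all copies
  restores the original genome byte-for-byte.
- **Library**: the nested primer targets one element terminus, so each
  copy is read from the side its orientation dictates — one flank class
  per site, as in the real protocol. Pair counts per copy are
  Poisson(100); fragments are uniform 400–600 bp; read 1 is the terminal
  15-mer plus flank (150 bp total), read 2 the fragment's far end;
  substitutions occur at 10⁻³ per base with constant Phred-37 qualities.
- **DEG table**: designated up-regulated (storage-protein role) and
  down-regulated (photosynthesis role) genes get |log2fc| in 1.5–4 and
  small adjusted p-values; all other genes get null effects.

What the simulation does *not* emulate: sequence-composition bias, indels
and quality-correlated errors, chimeric amplicons, multiplexing artifacts,
repeat-induced multi-mapping, or a genome-scale gene count. Passing tests
therefore demonstrate the correctness of the algorithms and their
thresholds under controlled conditions, not performance on real MiSeq
libraries; quantities that depend on the real accessions and the full rice
annotation (per-line totals in the hundreds, genome-scale DEG fractions
below 1%) are out of reach at this scale by construction.

## Determinism and problem sizes

All randomness flows from one integer seed through per-stage
`numpy.random` generators (line-specific streams use a CRC-32 of the line
id, keeping everything stable across processes). Identical configuration
and seed give byte-identical outputs, which the manifest checksums make
checkable. Default problem sizes (300-kb genome, ~90 distinct sites,
~9,000 read pairs) complete the full pipeline in a few seconds and were
chosen so every validation runs comfortably on a laptop; they scale
linearly for larger experiments.
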