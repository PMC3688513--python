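# Methods

`linccat` implements a discovery-and-characterization procedure for long
intergenic noncoding RNAs (lincRNAs) from assembled RNA-seq transcript
models, together with a seeded synthetic-data generator that plants ground
truth for every rule the procedure applies. This note records the model,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic tests do and do not establish.

## The discovery cascade

Candidate transcripts (blocked BED12 models, usually of ambiguous strand)
pass through six filters in a fixed order. A transcript is removed at the
first rule it violates, and the removal stage and reason are recorded per
transcript, so catalog provenance is fully attributable.

1. **Length.** Exonic (mature RNA) length < 200 nt removes the transcript.
   The threshold applies to the spliced length, not the genomic span,
   because the lincRNA definition is a statement about the RNA molecule.
2. **Protein-coding-gene proximity.** A transcript on the same strand as a
   protein-coding gene — or of ambiguous strand, which matches both
   strands — is removed when its span lies within 1 kb of the gene span
   (inclusive; overlap counts as distance zero). A transcript on the
   definite opposite strand is removed only if it overlaps the gene span
   by at least one base.
3. **Annotation overlap.** Any ≥1 bp span overlap with a non-lincRNA
   annotation (other genes, pseudogenes, small ncRNAs, alternative/extended
   UTRs), regardless of strand, removes the transcript.
4. **Coding potential.** All six reading frames of the spliced sequence are
   scanned. A "large ORF" is (i) a complete ATG→stop frame longer than
   100 aa (the stop codon is excluded from the count, so 101 aa is the
   smallest large ORF); (ii) an ATG followed by more than 300 stop-free
   in-frame nucleotides running off the transcript end (stop-truncated);
   or (iii) an in-frame stop more than 300 nt from the transcript start
   with no prior in-frame ATG or stop (start-truncated). The truncation
   rules catch ORFs whose start or stop lies outside the assembled model.
   Codons containing N never match a start or stop. Transcripts carrying a
   large ORF are removed in a first pass; a second pass removes remaining
   transcripts whose span overlaps a pass-one transcript (likely UTR
   fragments of the same coding unit). The second pass is deliberately
   non-transitive: a transcript touching only a pass-two victim survives.
5. **Extended gene boundaries.** Protein-coding gene spans widened by
   assembly evidence are a required input set; ≥1 bp strand-blind span
   overlap removes the transcript.
6. **Expression.** Reads are counted with *full assignment*: a read
   increments the count of every transcript whose exons its aligned blocks
   overlap by ≥1 bp, with no fractional splitting — redundant overlapping
   models of the same transcript must each receive the full evidence.
   FPKM = count · 10⁹ / (exonic length · total mapped reads). Transcripts
   never exceeding FPKM 1 (strict) in any dataset are removed; survivors
   are tiered at FPKM > 1, > 10, > 30, with tiers nested.

### Merging, grouping, naming

Survivors are merged into lincRNA "genes": two transcripts merge when some
exon pair overlaps by at least 50% of *either* exon's length (inclusive at
exactly 50%; the one-directional reading is the more-merging one and
produces the minimal catalog). Opposite definite strands never merge; any
pair involving an ambiguous strand may. Merging is taken to transitive
closure; each component becomes the union of member exons. Merged models
within 1 kb of each other (inclusive, transitively) share a group, and
models are named `FPKM{tier}_group_{g}_transcript_{t}` with groups and
transcripts numbered by leftmost coordinate — the only tie-break rule the
naming needs, chosen for determinism. Strand is inferred from splice
junction dinucleotides (GT..AG forward, CT..AC reverse) only when all
junctions agree; single-exon models and conflicts stay ambiguous. FPKMs
are recomputed on the merged exon unions.

### Expression above intergenic background

The background space is the uniquely-mappable genome minus every
annotation carrying evidence of transcription; residual intervals must be
longer than 200 bp. Size-matched annotations (a query's exact block
structure) are translated to a start chosen uniformly over all eligible
positions on any chromosome, and their FPKMs — computed with the same
full-assignment counter and the dataset's mapped-read total — form a
per-dataset null. The p-value uses the add-one permutation estimator,
p = (1 + #{null ≥ observed}) / (1 + n_shuffles), which can never return
zero. Bonferroni correction multiplies by the number of datasets (one test
per dataset); a transcript is significant at corrected p ≤ 0.1 in at least
one dataset. The pipeline default is 2,000 shuffles per dataset — at the
simulated genome scale the null is already stable there; the module accepts
any count.

### Characterization

* **Ribosome engagement**: 30-nt windows tile the spliced transcript with a
  1-nt offset; per window, the ratio of ribosome-profiling to RNA-seq reads
  (≥1 bp overlap counts a read). Windows with zero RNA-seq reads are
  skipped rather than scored infinite, so maxima stay comparable across
  transcripts; the transcript score is the maximum ratio, undefined when no
  window has RNA coverage.
* **Conservation**: the maximum mean score over 50-nt windows in which all
  50 consecutive spliced bases carry scores; transcripts without 50
  contiguously scored bases are undefined rather than zero.
* **Trait-associated SNP (TAS) enrichment**: tested-SNP denominators are
  platform-scaled (0.586 × Illumina-tested + 0.414 × Affymetrix-tested;
  dual-platform SNPs count in both terms); the rate is TAS per scaled
  tested SNP, compared between regions as a fold with Fisher's exact test
  on the 2×2 table (scaled totals rounded to integers — the rounding error
  is at most half a count) and Wilson 95% intervals per rate (well behaved
  at small counts, the method being otherwise unspecified).
* **Common-SNP density**: common-flagged SNPs per region base.
* **PolyA bimorphism**: features with reads in all four datasets and
  FPKM > 1 in at least one fraction per cell type are scored by
  FPKM⁺/FPKM⁻; agreement across cell types is Pearson r on log₂ ratios
  (ratios are multiplicative; the log makes the comparison symmetric).
* **ChIP signal**: depth-normalized IP/input count ratio over the
  transcript, undefined (not infinite) at zero input.
* **PET end support**: a transcript end is supported when its terminal base
  falls inside the corresponding end block of an overlapping cluster of
  compatible strand; ambiguous-strand transcripts are tested under both
  orientations.
* **Tissue clustering**: features at FPKM > 10, log₂(FPKM + 1) transformed
  (the +1 pseudo-count keeps zero FPKM at zero), then alternately rescaled
  row-then-column toward unit sum of squares, followed by Euclidean
  distances between samples and centroid linkage. Exact unit sum of squares
  in every row *and* column is impossible for a non-square matrix — the
  total would have to equal both dimensions — so the alternation converges
  to a limit cycle in which the final (column) pass is exact and row norms
  equalize within connected blocks of the matrix's support. The procedure
  ends on the column pass; tests assert convergence of the alternation and
  exact unit columns.

## The synthetic study conditions

The generator's defaults define the conditions under which the pipeline is
validated: a 2 × 1 Mb genome with a mappability mask excluding 10% of bases
in 50–500 bp segments; 60 protein-coding genes with real 120–180-codon
ORFs; 150 true lincRNAs (spliced and single-exon, 400–1,200 nt mature
length, verified ORF-free against the scanner at generation time, placed
more than 1 kb from genes in mappable space); and 350 decoys, each built to
violate exactly one cascade rule (50 short, 50 proximity, 40 pseudogene-
overlapping, 40 small-ncRNA-overlapping, 40 UTR-extension-overlapping, 50
large-ORF, 30 ORF-neighbor, 20 extended-gene, 30 low-expression). Six
RNA-seq datasets cover three tissues × two polyA fractions at 10⁷ mapped
reads each.

Expression is log-normal (lincRNA median ≈ 20 FPKM, σ ≈ 0.6, clipped to
[8, 300]) with tissue-specific on/off patterns (one or two of three
tissues), per-tissue log-normal jitter, and a per-transcript polyA ratio
that splits signal between fractions (genes biased to polyA⁺ at ratio ≈ 4,
lincRNAs centered on 1, i.e. bimorphic). Read counts are Poisson around the
FPKM-implied mean — the simplest model consistent with the FPKM definition;
over-dispersion would not change what the cascade's logic is being tested
for. Reads are placed uniformly along the spliced transcript and emitted as
split alignments when they cross junctions. Low-expression decoys are
calibrated to FPKM 0.15–0.30 flat across datasets (no tissue or fraction
multipliers), which keeps the probability of a Poisson excursion above the
FPKM 1 count threshold negligible at these library depths.

Intergenic noise reads follow a regional log-normal rate field (per-5-kb
window multipliers, σ = 1.5, base rate 0.6–1.5 reads/kb by library type,
polyA⁻ noisiest). Regional variation matters twice: it reproduces the
polyA⁺-libraries-are-cleaner read-distribution signature, and it makes the
shuffled-annotation null near-continuous enough for empirical p-value
calibration to be a meaningful test — a homogeneous Poisson noise floor
would tie most null values at a handful of small counts. Noise reads never
overlap planted feature spans, so background loci are genuinely
non-expressed up to noise and the low-expression guarantee is exact.

The conservation track is zero-mean unit-variance Gaussian noise over
mappable bases, elevated by +2 across coding CDS exons and across one
100-bp window in half of the true lincRNAs. SNP tables scatter 10,000
tested SNPs uniformly (platforms 45% Illumina / 35% Affymetrix / 20% both)
with trait-associated flags at a 1% background rate and a planted 5-fold
enrichment inside lincRNA exons. PET clusters mark the true ends of 60
genes/lincRNAs; ChIP IP reads are enriched 5-fold over planted mark
intervals against a uniform input.

Randomness is split into named streams (genome, sequence, annotation,
reads, tracks, snps, extras), each seeded from the master seed, so adding a
dataset cannot perturb annotation placement; a fixed seed makes every
output byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing errors and quality scores, fragment-
length and positional bias, over-dispersed biological replication,
isoform structure within a locus, repeat-driven multi-mapping (the mask is
random rather than repeat-derived), linkage disequilibrium among SNPs, and
genomes at chromosome scale. The cascade's *logic* is what is validated;
its real-data operating characteristics are not.

## Numerical and boundary choices

* Coordinates are 0-based half-open everywhere internally; SNP table
  positions are 1-based in files and converted at the reader boundary.
* Abutting or overlapping exons in one input record are unioned before any
  computation.
* "Within 1 kb" is inclusive (≤ 1000) in both the proximity filter and
  grouping: a boundary had to be fixed, and the inclusive reading is the
  conservative (more-removing, more-grouping) one.
* Background intervals must be strictly longer than 200 bp.
* Depth profiles are dense per-chromosome integer vectors with the
  mappability mask applied at query time — at the few-Mb simulated scale
  this is simpler and faster than run-length storage, and the mask-at-query
  rule means a read partially outside the mask contributes only its masked
  bases to coverage fractions.
* Window scores live in transcript coordinates and are projected to
  genomic blocks for counting, so windows never straddle introns.
* The empirical-p estimator adds one to numerator and denominator; p-values
  are never zero regardless of shuffle count.

## Problem sizes

The default configuration (the acceptance surface) runs the full pipeline
in well under a minute on one CPU: ~460,000 simulated reads across six
datasets, 500 candidate transcripts, 2,000 shuffles per dataset for the
background null. Oracle cross-checks use 200 random sequences for the ORF
scanner, 50 fixtures of up to 200 transcripts for merge/group closure, a
10 kb toy genome with 500 reads for coverage, 500 true-null queries against
a 1,000-shuffle null for calibration, and 20 replicate SNP tables for
enrichment recovery.

## Known limitations

* The cascade consumes already-assembled transcript models; alignment and
  assembly are upstream of this package.
* Codon-substitution coding scores (PhyloCSF-style) are not implemented;
  coding potential rests on the ORF rules alone.
* Fisher's exact test on platform-scaled (hence rounded) tested-SNP counts
  is an approximation wherever the scaled totals are far from integers.
* The clustering module reports distances and a merge list; rendering is
  out of scope.
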