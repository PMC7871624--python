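# Methods

## Model

The dispensability score treats read coverage as a proxy for gene
presence. For gene g and genome (accession) n,

    ds(g) = 1 / [ (1/N) · Σₙ cov(g, n) / m(n) ],    n = 1 … N,

where cov(g, n) is the mean aligned read depth over the full gene span
and m(n) is genome n's genic mean — the **unweighted** arithmetic mean
of per-gene coverages, not the length-weighted total genic depth. The
unweighted mean is the literal reading of the equation's denominator
("average coverage over all genes"); a length-weighted variant would
change scores whenever long and short genes differ systematically in
coverage, and is deliberately not offered.

Assumptions worth keeping in mind when interpreting scores:

- Coverage is proportional to copy number. Mapping artefacts (repeats,
  paralogs, plastid-like contamination) violate this and show up as
  scores far below 1 rather than as errors.
- Genomes are exchangeable draws from the clade of interest. A biased
  panel biases every score.
- The same mapper and parameters were used for every genome in a run;
  the `mapper-correlation` check quantifies how much the choice of
  mapper moves per-gene coverage (rank correlation of per-gene
  averages).

An all-zero gene row gives ds = +∞. Infinity is a legal primary result
and is serialised as `inf`; `cap_infinite_scores` replaces it by the
largest finite score as an explicit opt-in step (the downstream
statistics require finite samples), never inside the score definition.

## Pipeline and parameters

1. **Coverage (components I–II).** One SAM/BAM per genome is streamed
   once; a record contributes the reference positions its CIGAR
   consumes and covers (M/=/X/D; N skips, I/S/H/P contribute nothing).
   Unmapped, secondary and supplementary records are excluded.
   Duplicates are counted and the MAPQ threshold defaults to 0
   (`--min-mapq`): the published procedure only states that secondary
   alignments were discarded, and anything stricter would silently
   change scores, so both knobs are exposed but off. Streaming with
   per-chromosome interval trees makes sorting/indexing unnecessary;
   the per-gene sum of read overlaps equals the per-position depth sum
   exactly.
2. **Genome filter (component III).** Genomes with genic mean < cutoff
   (default 10×) are discarded; the comparison is strict, so a genome
   at exactly the cutoff is kept. The cutoff applies to the genic mean
   — the same statistic used as the normalising denominator — and must
   be > 0, which also guards the later division. If every genome fails,
   the run aborts ("no genomes pass coverage cutoff").
3. **Matrix and score (components IV–V).** The genes × genomes matrix
   is normalised column-wise by the genic means (each column then
   averages to 1) and reduced gene-major in double precision; summation
   order is fixed for bit-reproducibility.
4. **Reports and figures (component VI).** Score TSV (gene_id, score,
   zero-coverage count, capped flag), composition table, histogram
   (equal-width bins, log-scaled counts, bars coloured by bin
   midpoint), box plot (mean dashed, median solid), and a genome-wide
   heatmap. All plots write TSV sidecars with the exact numbers drawn,
   so correctness checks never touch pixels.

Composition table: the "top/bottom 10%" coverage groups use
k = ⌈0.1·N⌉ values with a floor of 1 — the ceiling guarantees nonempty
groups for any N (for N < 10 they reduce to max/min). Ranking is per
gene over its N coverage values, ties broken by genome column order.

Heatmap: genes are assigned to half-open [i·b, (i+1)·b) bins of their
midpoint (b = 100 kb by default; a midpoint exactly on a boundary falls
right); bin colour is the mean score, empty bins are neutral grey,
centromeres are black dots. Binned means rather than per-gene ticks
keep the track readable at genome scale.

## Validation statistics

- **Group comparison** (conserved single-copy orthologs vs rest, TE
  genes vs rest): two-sided Mann–Whitney U — exact enumeration for
  tie-free samples with both sizes ≤ 8, tie-corrected normal
  approximation otherwise; identical samples short-circuit to p = 1 —
  plus Levene's test for equal variances in the mean-centred
  (classical) variant, matching the SciPy default the published
  analysis used; a median-centred option exists in SciPy but is not
  the default here. Groups containing infinite scores are refused:
  capping is required first, making the treatment of the one infinite
  gene explicit instead of implicit. Degenerate inputs (both groups
  constant, or a singleton group) flag the Levene result
  not-applicable instead of crashing.
- **Replicate variance.** Scores from a replicate-only matrix
  (technical replicates of one accession) are compared with scores
  from 100 random subsets of n = 14 genome columns drawn without
  replacement from the full panel (independently across iterations,
  seeded). Levene's test runs between the replicate score sample and
  the pooled subset scores — pooling yields the single p-value the
  analysis is meant to produce. Variances are sample variances
  (ddof = 1).
- **Nearest-feature distance.** Edge-to-edge base pairs on 1-based
  inclusive intervals, d = max(0, b.start − a.end, a.start − b.end):
  overlap gives 0, book-ended neighbours give 1. A gene in the
  reference set is compared against the others only; chromosomes
  without any reference feature yield NaN. The module exports the
  predictor table (score, TE distance, gene length, exon count) for
  external regression; the regression itself is out of scope.

## Synthetic data

`PangenomeSpec` draws coverage(g, n) = depth(n) · copy(g, n) ·
presence(g, n) · noise(g, n). Presence is Bernoulli(1 − f) per PAV gene
per genome; noise is multiplicative lognormal with unit mean and a
given coefficient of variation (coverage is positive and right-skewed,
which a normal error model would violate at low depth). One RNG stream
per genome (spawned from a single seed) keeps draws for genome j
independent of the panel size. Defaults emulate a resequencing panel:
depths of 12–40× around the 10× filter cutoff, technical noise
CV ≈ 0.05 for replicates of one accession, PAV genes at absence
fraction 0.5 for heterogeneous panels.

What the generator does **not** emulate: mapping errors, repeat-induced
coverage inflation, GC or fragmentation bias, plastid contamination,
partial gene deletions. Passing tests therefore demonstrate that the
arithmetic pipeline is exact and that the score separates depth noise
from presence/absence signal under clean conditions — not that the
score is robust to real-world mapping artefacts, which the published
validation addressed with real data at three orders of magnitude larger
scale.

`expected_scores_oracle` is a loop-level transcription of the score
equation over the noise-free expected coverages, kept independent of
the scoring module so the two code paths check each other. One of its
consequences, asserted in the tests: a gene absent from k of N genomes
(all else uniform single-copy) scores exactly N/(N−k); the genic-mean
depression in the k genomes inflates the *other* genes' normalised
coverage instead, pushing their scores below 1.

`emit_alignment_fixture` realises a noise-free spec as a reference
FASTA, a GFF3 and one SAM per genome: each present gene receives
exactly depth · copy full-length, perfectly aligned primary reads
(MAPQ 60, CIGAR `<L>M`), so the alignment path reproduces the simulated
matrix bit-for-bit. Effective depths must be integers; noisy specs are
rejected — the fixture tests coverage arithmetic, not mapper behaviour.

## Numerical choices and problem sizes

All reductions are double precision, plain arithmetic means. Matrix
round-trips through TSV use `repr` serialisation and are lossless to
1e−12 relative. Test suites use matrices up to 966 genomes for the
worked example and 200 random matrices per invariance property; the
replicate-variance property runs 100 seeded reruns of a
120-gene / 40-genome panel with 100 subset iterations each. The whole
suite completes in well under a minute on one core.

## Known limitations

- CRAM input, exon-resolution coverage and per-base track export are
  not supported.
- The genome filter uses genic mean coverage; whole-genome mean
  coverage (including intergenic space) would differ on real data and
  is not offered.
- Scores for repeat-rich and (peri-)centromeric genes inherit every
  short-read mapping ambiguity; the score quantifies coverage, not
  biological dispensability, in those regions.
- Mixed-model fits relating scores to TE distance, gene length or exon
  number are intentionally external; only their predictor table is
  produced.
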