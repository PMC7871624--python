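# quod

Reference-based quantification of gene dispensability from read-mapping
coverage.

## The problem

Pangenome studies traditionally classify genes as *core* (present in
every investigated genome) or *dispensable*/*accessory* (present in only
some), using arbitrary presence/absence cutoffs. `quod` replaces that
binary call with a continuous per-gene **dispensability score** computed
from short-read coverage: reads from many individuals (accessions) of a
clade are mapped to one high-quality reference, and for every annotated
gene the mean read depth in every genome is converted into a single
score. It is aimed at plant pangenomics but applies to any clade with a
good reference sequence and resequencing data for many individuals.

## The score

Let cov(g, n) be the mean read depth over the span of gene g in genome
n, and let the *genic mean* of genome n be the unweighted mean of
cov(·, n) over all genes. After discarding genomes whose genic mean is
below a cutoff (default 10), the dispensability score of gene g over the
N retained genomes is

```
ds(g) = 1 / [ (1/N) · Σₙ  cov(g, n) / genic_mean(n) ]
```

Dividing by the genic mean removes sequencing-depth differences between
genomes, so the score is invariant under rescaling any genome's
coverage. Interpretation:

- **ds ≈ 1** — single-copy gene present in essentially all genomes (core),
- **ds ≫ 1** — gene absent from many genomes (dispensable); a gene with
  normalised coverage 1 in a fraction *p* of genomes and 0 elsewhere
  scores exactly 1/*p*,
- **ds < 1** — locus with excess coverage (copy-number amplification,
  collapsed repeats, or plastid-like contamination),
- **ds = ∞** — zero coverage in every retained genome; an explicit
  capping step replaces infinities with the largest finite score.

## Worked example

The synthetic generator produces coverage matrices with known
presence/absence (PAV) and copy-number (CNV) ground truth:

```python
from quod import synthetic, scoring

spec = synthetic.PangenomeSpec(
    n_genes=6, n_genomes=200,
    pav_genes={0: 0.9, 1: 0.5},        # genes absent from 90% / 50% of genomes
    cnv_genes={2: 2.0},                # gene duplicated everywhere
    depth_per_genome=[float(12 + j % 25) for j in range(200)],
    seed=4,
)
matrix, truth = synthetic.simulate_coverage_matrix(spec)
scores = scoring.score_pipeline(matrix, cutoff=10)
for gene_id, ds in scores.scores.items():
    absent = int((truth.presence.loc[gene_id] == 0).sum())
    print(f"{gene_id}  ds = {ds:6.3f}   absent in {absent:3d}/200 genomes")
```

prints

```
g0  ds = 11.290   absent in 181/200 genomes
g1  ds =  2.006   absent in  99/200 genomes
g2  ds =  0.462   absent in   0/200 genomes
g3  ds =  0.924   absent in   0/200 genomes
g4  ds =  0.924   absent in   0/200 genomes
g5  ds =  0.924   absent in   0/200 genomes
```

g0 is carried by 19 of 200 genomes and scores ≈ 200/19 ≈ 10.5 (the
deviation from 11.3 comes from the genic-mean shifts the absences
induce); g1 is absent from half the genomes and scores ≈ 2; the
duplicated g2 scores below 1; the ordinary genes sit near 1, pushed
slightly below it because the duplication inflates every genic mean.

## Command line

The same workflow is available as a CLI over finished alignments (one
SAM/BAM per genome, all mapped to the same reference) plus a GFF3
annotation, or over a precomputed coverage matrix:

```bash
quod score --in mappings/ --gff annotation.gff3 --out run/ --visualize
quod score --matrix run/coverage_matrix.tsv --out run2/
quod composition --matrix run/coverage_matrix.tsv \
     --scores run/dispensability_scores.tsv --genes gene17 --out comp/ --plot
quod compare-groups --scores run/dispensability_scores.tsv --group busco_ids.txt
quod replicate-variance --replicates col0.tsv --full panel.tsv --seed 1
quod te-distance --gff annotation.gff3 --te-genes te_ids.txt \
     --scores run/dispensability_scores.tsv --out predictors.tsv
quod mapper-correlation --matrix-a bwa.tsv --matrix-b bowtie2.tsv
quod simulate --genes 50 --genomes 10 --alignments --out fixture/
```

`score` persists every intermediate (coverage matrix, discarded-genome
list, score table, run manifest) and optionally the score histogram and
box plot; a genome-wide heatmap with centromere marks is available
through `quod.visualization`. Exit codes: 0 success, 2 usage error,
3 validation error, 4 I/O error.

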