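"""Shared fixtures: tiny hand-written GFF3/SAM inputs and random matrices."""

import numpy as np
import pandas as pd
import pytest

from quod.models import CoverageMatrix

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:Chr1\tLN:10000\n"


def make_matrix(values, gene_ids=None, genome_ids=None) -> CoverageMatrix:
    arr = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    genome_ids = genome_ids or [f"s{j}" for j in range(arr.shape[1])]
    frame = pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene_id"), columns=genome_ids)
    return CoverageMatrix(frame)


def sam_record(qname, pos, cigar, flag=0, mapq=60, rname="Chr1"):
    return f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*\n"


@pytest.fixture
def write_sam(tmp_path):
    counter = iter(range(10_000))

    def _write(records, header=SAM_HEADER, name=None):
        name = name or f"aln{next(counter)}.sam"
        path = tmp_path / name
        path.write_text(header + "".join(records))
        return path

    return _write


@pytest.fixture
def simple_gff(tmp_path):
    """One gene (Chr1:101-200) with mRNA/exon children, plus a second gene."""
    path = tmp_path / "genes.gff3"
    path.write_text(
        "##gff-version 3\n"
        "Chr1\ttest\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        "Chr1\ttest\tmRNA\t101\t200\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "Chr1\ttest\texon\t101\t150\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1\n"
        "Chr1\ttest\texon\t161\t200\t.\t+\t.\tID=g1.t1.e2;Parent=g1.t1\n"
        "Chr1\ttest\tgene\t501\t700\t.\t-\t.\tID=g2\n"
        "Chr1\ttest\tmRNA\t501\t700\t.\t-\t.\tID=g2.t1;Parent=g2\n"
        "Chr1\ttest\texon\t501\t700\t.\t-\t.\tID=g2.t1.e1;Parent=g2.t1\n"
    )
    return path


def literal_score_transcription(coverage: np.ndarray) -> np.ndarray:
    """Loop-level transcription of the score equation, used as test oracle.

    ds(g) = 1 / [ sum_n ( cov(g,n) / mean_g' cov(g',n) ) / N ]
    """
    n_genes, n_genomes = coverage.shape
    out = np.empty(n_genes)
    genic_means = [sum(coverage[g, n] for g in range(n_genes)) / n_genes for n in range(n_genomes)]
    for g in range(n_genes):
        total = 0.0
        for n in range(n_genomes):
            total += coverage[g, n] / genic_means[n]
        mean_norm = total / n_genomes
        out[g] = 1.0 / mean_norm if mean_norm > 0 else np.inf
    return out
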