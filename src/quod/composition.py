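"""Decompose per-gene scores into their coverage constituents.

For a gene of interest the composition table reports the score, the mean
coverage over all retained genomes, the means over the genomes with the
highest and lowest 10% of coverage values (group size k = ceil(0.1 * N),
at least 1), the number of genomes with zero coverage, and the raw
coverage of every genome. A high score driven by many exact zeros reads
differently from one driven by uniformly shallow coverage; this table
makes that distinction visible.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, ValidationError
from .models import CoverageMatrix, DispensabilityScores


@dataclass
class CompositionRecord:
    gene_id: str
    dispensability_score: float
    mean_coverage_all: float
    mean_top10: float
    mean_bottom10: float
    n_zero: int
    per_genome: pd.Series


def percentile_group_size(n_genomes: int) -> int:
    """k = ceil(0.1 * N), floored at 1, for the top/bottom coverage groups."""
    return max(1, math.ceil(0.1 * n_genomes))


def build_composition_table(
    matrix: CoverageMatrix,
    scores: DispensabilityScores,
    gene_ids: list[str] | None = None,
) -> list[CompositionRecord]:
    """One :class:`CompositionRecord` per requested gene.

    ``matrix`` must be the filtered matrix the scores were computed from.
    Ties in the coverage ranking are broken by genome column order
    (stable sort), so the result is deterministic.
    """
    if gene_ids is None:
        gene_ids = matrix.gene_ids
    unknown = [g for g in gene_ids if g not in matrix.values.index]
    if unknown:
        raise ValidationError(f"unknown gene ids: {unknown}")
    missing_scores = [g for g in gene_ids if g not in scores.scores.index]
    if missing_scores:
        raise ValidationError(f"gene ids without scores: {missing_scores}")
    n = matrix.n_genomes
    k = percentile_group_size(n)
    records = []
    for gene_id in gene_ids:
        row = matrix.values.loc[gene_id]
        values = row.to_numpy(dtype=float)
        order = np.argsort(values, kind="stable")
        sorted_vals = values[order]
        records.append(
            CompositionRecord(
                gene_id=gene_id,
                dispensability_score=float(scores.scores[gene_id]),
                mean_coverage_all=float(values.mean()),
                mean_top10=float(sorted_vals[-k:].mean()),
                mean_bottom10=float(sorted_vals[:k].mean()),
                n_zero=int((values == 0).sum()),
                per_genome=row.copy(),
            )
        )
    return records


def write_composition_table(
    records: list[CompositionRecord], path: str | os.PathLike
) -> Path:
    """TSV report: summary columns followed by one coverage column per genome."""
    if not records:
        raise ParameterError("no composition records to write")
    path = Path(path)
    genome_ids = list(records[0].per_genome.index)
    try:
        with open(path, "w") as handle:
            header = [
                "gene_id",
                "dispensability_score",
                "mean_coverage_all",
                "mean_top10",
                "mean_bottom10",
                "n_zero",
            ] + genome_ids
            handle.write("\t".join(header) + "\n")
            for rec in records:
                score = "inf" if np.isinf(rec.dispensability_score) else repr(rec.dispensability_score)
                fields = [
                    rec.gene_id,
                    score,
                    repr(rec.mean_coverage_all),
                    repr(rec.mean_top10),
                    repr(rec.mean_bottom10),
                    str(rec.n_zero),
                ] + [repr(float(v)) for v in rec.per_genome.loc[genome_ids]]
                handle.write("\t".join(fields) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write composition table to {path}: {exc}") from exc
    return path


def plot_gene_coverage_distribution(
    matrix: CoverageMatrix, gene_ids: list[str], out_path: str | os.PathLike
):
    """Box plot of per-genome coverage, one box per requested gene.

    Returns the list of per-gene coverage arrays that were plotted, so
    callers and tests can assert on data rather than pixels.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not gene_ids:
        raise ParameterError("no genes requested for the coverage box plot")
    unknown = [g for g in gene_ids if g not in matrix.values.index]
    if unknown:
        raise ValidationError(f"unknown gene ids: {unknown}")
    data = [matrix.values.loc[g].to_numpy(dtype=float) for g in gene_ids]
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(gene_ids) + 2), 4))
    ax.boxplot(data, tick_labels=gene_ids)
    ax.set_ylabel("per-gene mean coverage")
    ax.set_xlabel("gene")
    fig.tight_layout()
    try:
        fig.savefig(out_path)
    except OSError as exc:
        raise InputError(f"cannot write plot to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    return data
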