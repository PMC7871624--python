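"""Genome filtering, depth normalisation and the dispensability score.

For gene g over N retained genomes the score is

    ds(g) = 1 / [ (1/N) * sum_n  cov(g, n) / genic_mean(n) ]

where cov(g, n) is the mean read depth of gene g in genome n and
genic_mean(n) is the unweighted mean of per-gene coverages of genome n.
Division by the genic mean removes between-genome sequencing-depth
differences, so ds is invariant under rescaling any genome's column.
Ubiquitous single-copy genes score near 1, frequently absent genes score
high, and amplified or collapsed loci score below 1. A gene with zero
coverage in every retained genome scores +inf; capping that to the
largest finite score is an explicit post-processing step.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, ValidationError
from .models import CoverageMatrix, DispensabilityScores, NormalizedMatrix

DEFAULT_COVERAGE_CUTOFF = 10.0


def filter_low_coverage_genomes(
    matrix: CoverageMatrix, cutoff: float = DEFAULT_COVERAGE_CUTOFF
) -> tuple[CoverageMatrix, list[str]]:
    """Drop genomes whose genic mean coverage lies below ``cutoff``.

    The comparison is strict: a genome at exactly the cutoff is kept.
    Returns the filtered matrix and the discarded genome ids.
    """
    if cutoff <= 0:
        raise ParameterError(f"coverage cutoff must be > 0, got {cutoff}")
    means = matrix.genic_means
    kept = [g for g in matrix.genome_ids if means[g] >= cutoff]
    discarded = [g for g in matrix.genome_ids if means[g] < cutoff]
    if not kept:
        raise ValidationError("no genomes pass coverage cutoff")
    if not discarded:
        return matrix, []
    return matrix.subset_genomes(kept), discarded


def normalize_by_genome_mean(matrix: CoverageMatrix) -> NormalizedMatrix:
    """Divide each genome column by its genic mean coverage."""
    means = matrix.genic_means
    zero = [g for g, m in means.items() if m == 0]
    if zero:
        raise ValidationError(
            f"genomes with zero genic mean coverage: {zero}; "
            "filter low-coverage genomes first"
        )
    return NormalizedMatrix(matrix.values.div(means, axis=1))


def compute_dispensability_scores(
    normalized: NormalizedMatrix, discarded_genomes: list[str] | None = None
) -> DispensabilityScores:
    """Evaluate ds(g) for every gene of a normalised matrix.

    The per-gene mean over genomes is taken gene-major in double
    precision; its reciprocal is the score. An all-zero gene row yields
    +inf, which is a legal result and is propagated as such.
    """
    values = normalized.values.to_numpy(dtype=float)
    if values.shape[1] < 1:
        raise ValidationError("need at least one genome to compute scores")
    mean_norm = values.mean(axis=1)
    with np.errstate(divide="ignore"):
        scores = np.where(mean_norm > 0, 1.0 / mean_norm, np.inf)
    n_zero = (values == 0).sum(axis=1)
    index = normalized.values.index
    return DispensabilityScores(
        scores=pd.Series(scores, index=index, name="dispensability_score"),
        n_genomes_used=normalized.n_genomes,
        discarded_genomes=list(discarded_genomes or []),
        n_zero=pd.Series(n_zero, index=index, name="n_zero_coverage_genomes"),
    )


def cap_infinite_scores(scores: DispensabilityScores) -> DispensabilityScores:
    """Replace every infinite score by the largest finite score.

    Returns a new object; the ``was_infinite`` flags record which scores
    were replaced so the original values remain recoverable.
    """
    arr = scores.scores.to_numpy(dtype=float)
    infinite = np.isinf(arr)
    if infinite.all():
        raise ValidationError("all scores are infinite: no next highest score exists")
    if not infinite.any():
        return DispensabilityScores(
            scores=scores.scores.copy(),
            n_genomes_used=scores.n_genomes_used,
            discarded_genomes=list(scores.discarded_genomes),
            n_zero=None if scores.n_zero is None else scores.n_zero.copy(),
            was_infinite=scores.was_infinite.copy(),
        )
    cap = arr[~infinite].max()
    capped = np.where(infinite, cap, arr)
    return DispensabilityScores(
        scores=pd.Series(capped, index=scores.scores.index, name="dispensability_score"),
        n_genomes_used=scores.n_genomes_used,
        discarded_genomes=list(scores.discarded_genomes),
        n_zero=None if scores.n_zero is None else scores.n_zero.copy(),
        was_infinite=pd.Series(infinite, index=scores.scores.index),
    )


def score_pipeline(
    matrix: CoverageMatrix, cutoff: float = DEFAULT_COVERAGE_CUTOFF
) -> DispensabilityScores:
    """Filter, normalise and score in one call (components III–V)."""
    filtered, discarded = filter_low_coverage_genomes(matrix, cutoff=cutoff)
    normalized = normalize_by_genome_mean(filtered)
    return compute_dispensability_scores(normalized, discarded_genomes=discarded)


def write_scores(scores: DispensabilityScores, path: str | os.PathLike) -> Path:
    """Write scores as TSV: gene_id, score, zero-coverage count, capped flag.

    Infinite scores serialise as ``inf``.
    """
    path = Path(path)
    n_zero = scores.n_zero
    if n_zero is None:
        n_zero = pd.Series(-1, index=scores.scores.index)
    try:
        with open(path, "w") as handle:
            handle.write(
                "gene_id\tdispensability_score\tn_zero_coverage_genomes\twas_infinite\n"
            )
            for gene_id in scores.scores.index:
                value = scores.scores[gene_id]
                text = "inf" if np.isinf(value) else repr(float(value))
                handle.write(
                    f"{gene_id}\t{text}\t{int(n_zero[gene_id])}\t"
                    f"{bool(scores.was_infinite[gene_id])}\n"
                )
    except OSError as exc:
        raise InputError(f"cannot write scores to {path}: {exc}") from exc
    return path


def read_scores(path: str | os.PathLike) -> DispensabilityScores:
    """Read a score TSV written by :func:`write_scores`."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"score file not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DispensabilityScores(
        scores=frame["dispensability_score"].astype(float),
        n_genomes_used=0,
        n_zero=frame["n_zero_coverage_genomes"].astype(int),
        was_infinite=frame["was_infinite"].astype(bool),
    )
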