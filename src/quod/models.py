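"""Core in-memory containers: annotated genes, coverage matrices, scores.

A :class:`CoverageMatrix` is a genes × genomes table of per-gene mean read
depth. Each column belongs to one investigated genome (one mapping file);
its *genic mean* — the unweighted mean of that column — measures the
genome's sequencing depth over genic space and is both the genome-filter
statistic and the normalising denominator of the dispensability score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: identifier, reference sequence and 1-based inclusive span."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: illegal span {self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand {self.strand!r} not in {sorted(VALID_STRANDS)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeCoverageProfile:
    """Per-gene mean read depth for one genome (one alignment file)."""

    genome_id: str
    per_gene_coverage: pd.Series  # index: gene_id, values: mean depth >= 0

    def __post_init__(self) -> None:
        cov = self.per_gene_coverage
        if not isinstance(cov, pd.Series):
            self.per_gene_coverage = cov = pd.Series(cov, dtype=float)
        if cov.index.has_duplicates:
            dups = cov.index[cov.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in profile {self.genome_id!r}: {dups}")
        vals = cov.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"non-finite coverage in profile {self.genome_id!r}")
        if (vals < 0).any():
            raise ValidationError(f"negative coverage in profile {self.genome_id!r}")

    @property
    def genic_mean(self) -> float:
        """Unweighted mean of the per-gene coverages."""
        return float(self.per_gene_coverage.mean())


def _check_axis(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")
    if len(index) == 0:
        raise ValidationError(f"empty {what} axis")


class CoverageMatrix:
    """Dense genes × genomes matrix of per-gene mean coverage.

    Wraps a :class:`pandas.DataFrame` with gene ids as row index and genome
    ids as columns. Entries are finite and non-negative; labels are unique.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise ValidationError("CoverageMatrix expects a pandas DataFrame")
        _check_axis(values.index, "gene ids")
        _check_axis(values.columns, "genome ids")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("coverage matrix contains non-finite entries")
        if (arr < 0).any():
            raise ValidationError("coverage matrix contains negative entries")
        self._values = values.astype(float)

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def gene_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def n_genomes(self) -> int:
        return self._values.shape[1]

    @property
    def n_genes(self) -> int:
        return self._values.shape[0]

    @property
    def genic_means(self) -> pd.Series:
        """Per-genome unweighted mean of per-gene coverages (column means)."""
        return self._values.mean(axis=0)

    def subset_genomes(self, genome_ids: list[str]) -> "CoverageMatrix":
        missing = [g for g in genome_ids if g not in self._values.columns]
        if missing:
            raise ValidationError(f"unknown genome ids: {missing}")
        return CoverageMatrix(self._values.loc[:, genome_ids])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CoverageMatrix({self.n_genes} genes x {self.n_genomes} genomes)"


class NormalizedMatrix:
    """Coverage matrix after division of each column by its genic mean.

    By construction every column's mean over genes equals 1.
    """

    def __init__(self, values: pd.DataFrame):
        _check_axis(values.index, "gene ids")
        _check_axis(values.columns, "genome ids")
        arr = values.to_numpy(dtype=float)
        if (arr < 0).any() or not np.all(np.isfinite(arr)):
            raise ValidationError("normalised matrix entries must be finite and >= 0")
        col_means = arr.mean(axis=0)
        if not np.allclose(col_means, 1.0, atol=1e-9):
            raise ValidationError("normalised matrix column means deviate from 1")
        self._values = values.astype(float)

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def gene_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def n_genomes(self) -> int:
        return self._values.shape[1]


@dataclass
class DispensabilityScores:
    """Per-gene dispensability scores ds(g).

    ``scores`` maps gene_id to a positive real or ``+inf``; a score is
    infinite exactly when the gene had zero coverage in every retained
    genome. ``n_zero`` counts retained genomes with coverage exactly 0 per
    gene. ``was_infinite`` records which scores were capped by
    :func:`quod.scoring.cap_infinite_scores`.
    """

    scores: pd.Series
    n_genomes_used: int
    discarded_genomes: list[str] = field(default_factory=list)
    n_zero: pd.Series | None = None
    was_infinite: pd.Series | None = None

    def __post_init__(self) -> None:
        s = self.scores.astype(float)
        if s.index.has_duplicates:
            raise ValidationError("duplicate gene ids in scores")
        if (s.to_numpy() <= 0).any() or np.isnan(s.to_numpy()).any():
            raise ValidationError("scores must be positive (or +inf)")
        self.scores = s
        if self.was_infinite is None:
            self.was_infinite = pd.Series(False, index=s.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def n_infinite(self) -> int:
        return int(np.isinf(self.scores.to_numpy()).sum())

    @property
    def all_finite(self) -> bool:
        return self.n_infinite == 0
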