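"""Statistical validation of dispensability scores.

Covers four checks: comparing score distributions between contrasting
gene sets (conserved single-copy orthologs vs the rest, TE genes vs the
rest) with a Mann–Whitney U test and a Levene variance test; a
replicate-variance analysis that contrasts score variance among technical
replicates of one accession with score variance across random accession
subsets; minimal base-pair distances from genes to a reference feature
set; and Spearman rank correlation of per-gene coverage between two
mapping runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError, ValidationError
from .models import CoverageMatrix, DispensabilityScores, GeneModel
from .scoring import cap_infinite_scores, score_pipeline


@dataclass
class GroupComparisonResult:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    variance_a: float
    variance_b: float
    u_statistic: float
    u_pvalue: float
    levene_statistic: float  # NaN when not applicable
    levene_pvalue: float  # NaN when not applicable
    levene_applicable: bool = True


@dataclass
class VarianceComparisonResult:
    replicate_variance: float
    subset_variances: list[float]
    pooled_subset_variance: float
    levene_statistic: float
    levene_pvalue: float
    iterations: int
    subset_size: int
    seed: int
    replicate_scores: pd.Series = field(repr=False, default=None)
    pooled_subset_scores: np.ndarray = field(repr=False, default=None)


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """Plain-text gene-id list, one id per line, '#' comments allowed."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"gene list not found: {path}")
    members = set()
    with open(path) as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if line:
                members.add(line)
    if not members:
        raise ValidationError(f"gene list {path} contains no gene ids")
    return members


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # exact enumeration for small tie-free samples, tie-corrected normal
    # approximation otherwise; identical samples carry no evidence (p = 1)
    if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
        return len(a) * len(b) / 2.0, 1.0
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(len(a), len(b)) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    pvalue = float(res.pvalue)
    if np.isnan(pvalue):  # zero-variance normal approximation
        pvalue = 1.0
    return float(res.statistic), min(pvalue, 1.0)


def compare_score_groups(
    scores: DispensabilityScores,
    group_members: set[str],
    labels: tuple[str, str] = ("group", "rest"),
) -> GroupComparisonResult:
    """Two-sided Mann–Whitney U plus Levene variance test, group vs rest.

    Scores must be finite; run :func:`quod.scoring.cap_infinite_scores`
    first. When both groups have zero variance the Levene statistic is
    undefined and flagged not-applicable instead of raising.
    """
    if not scores.all_finite:
        raise ValidationError(
            "scores contain infinite values; run cap_infinite_scores before group comparison"
        )
    unknown = sorted(group_members - set(scores.gene_ids))
    if unknown:
        raise ValidationError(f"group members absent from scores: {unknown}")
    mask = scores.scores.index.isin(group_members)
    a = scores.scores.to_numpy(dtype=float)[mask]
    b = scores.scores.to_numpy(dtype=float)[~mask]
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be nonempty")
    u_stat, u_p = _mannwhitney(a, b)
    var_a = float(np.var(a, ddof=1)) if len(a) > 1 else 0.0
    var_b = float(np.var(b, ddof=1)) if len(b) > 1 else 0.0
    if (var_a == 0.0 and var_b == 0.0) or min(len(a), len(b)) < 2:
        lev_stat, lev_p, applicable = float("nan"), float("nan"), False
    else:
        lev = stats.levene(a, b, center="mean")
        lev_stat, lev_p, applicable = float(lev.statistic), float(lev.pvalue), True
    return GroupComparisonResult(
        group_a_label=labels[0],
        group_b_label=labels[1],
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        variance_a=var_a,
        variance_b=var_b,
        u_statistic=u_stat,
        u_pvalue=u_p,
        levene_statistic=lev_stat,
        levene_pvalue=lev_p,
        levene_applicable=applicable,
    )


def replicate_variance_analysis(
    replicate_matrix: CoverageMatrix,
    full_matrix: CoverageMatrix,
    subset_size: int = 14,
    iterations: int = 100,
    seed: int = 0,
    cutoff: float = 10.0,
) -> VarianceComparisonResult:
    """Score variance among replicates vs random genome subsets.

    Scores are computed on the replicate matrix (filter, normalise,
    score, cap). Then, ``iterations`` times, ``subset_size`` genome
    columns are drawn without replacement from the full matrix, scored
    the same way, and the per-iteration score variance recorded. Levene's
    test compares the replicate score sample against the pooled subset
    scores. Bit-reproducible for a fixed seed.
    """
    if subset_size > full_matrix.n_genomes:
        raise ParameterError(
            f"subset_size {subset_size} exceeds number of genomes {full_matrix.n_genomes}"
        )
    if set(replicate_matrix.gene_ids) != set(full_matrix.gene_ids):
        raise ValidationError("replicate and full matrices must share a gene set")
    if iterations < 1:
        raise ParameterError("iterations must be >= 1")

    replicate_scores = cap_infinite_scores(score_pipeline(replicate_matrix, cutoff=cutoff))
    rep = replicate_scores.scores.to_numpy(dtype=float)
    replicate_variance = float(np.var(rep, ddof=1))

    rng = np.random.default_rng(seed)
    genome_ids = np.array(full_matrix.genome_ids)
    subset_variances: list[float] = []
    pooled: list[np.ndarray] = []
    for _ in range(iterations):
        chosen = rng.choice(genome_ids, size=subset_size, replace=False)
        sub_scores = cap_infinite_scores(
            score_pipeline(full_matrix.subset_genomes(list(chosen)), cutoff=cutoff)
        )
        arr = sub_scores.scores.to_numpy(dtype=float)
        subset_variances.append(float(np.var(arr, ddof=1)))
        pooled.append(arr)
    pooled_arr = np.concatenate(pooled)
    lev = stats.levene(rep, pooled_arr, center="mean")
    return VarianceComparisonResult(
        replicate_variance=replicate_variance,
        subset_variances=subset_variances,
        pooled_subset_variance=float(np.var(pooled_arr, ddof=1)),
        levene_statistic=float(lev.statistic),
        levene_pvalue=float(lev.pvalue),
        iterations=iterations,
        subset_size=subset_size,
        seed=seed,
        replicate_scores=replicate_scores.scores,
        pooled_subset_scores=pooled_arr,
    )


def nearest_feature_distances(
    genes: list[GeneModel], reference_features: list[GeneModel]
) -> pd.Series:
    """Minimal edge-to-edge distance (bp) from each gene to a reference feature.

    Intervals are 1-based inclusive; overlapping intervals have distance
    0 and adjacent intervals distance 1. A gene that itself appears in
    the reference set (same gene_id) is compared against the others
    only. Genes on a reference sequence without any feature get NaN.
    """
    if not reference_features:
        raise ParameterError("reference feature list is empty")
    prepared: dict[str, list[GeneModel]] = {}
    for feat in reference_features:
        prepared.setdefault(feat.seq_id, []).append(feat)
    for feats in prepared.values():
        feats.sort(key=lambda f: f.start)

    out = {}
    for gene in genes:
        feats = prepared.get(gene.seq_id)
        best = np.inf
        if feats:
            for feat in feats:
                if feat.gene_id == gene.gene_id:
                    continue
                d = max(0, feat.start - gene.end, gene.start - feat.end)
                if d < best:
                    best = d
                if best == 0:
                    break
        out[gene.gene_id] = best if np.isfinite(best) else np.nan
    return pd.Series(out, name="distance_to_nearest_feature", dtype=float)


def coverage_rank_correlation(
    matrix_a: CoverageMatrix, matrix_b: CoverageMatrix
) -> tuple[float, float]:
    """Spearman correlation of per-gene average coverage between two runs.

    Each gene's coverage is first averaged across genomes within each
    matrix; ranks use average-rank tie handling.
    """
    if set(matrix_a.gene_ids) != set(matrix_b.gene_ids):
        raise ValidationError("matrices must share an identical gene set")
    mean_a = matrix_a.values.mean(axis=1)
    mean_b = matrix_b.values.mean(axis=1).loc[mean_a.index]
    if np.unique(mean_a.to_numpy()).size == 1 or np.unique(mean_b.to_numpy()).size == 1:
        raise ValidationError("correlation undefined: per-gene averages are constant")
    rho, pvalue = stats.spearmanr(mean_a.to_numpy(), mean_b.to_numpy())
    return float(rho), float(pvalue)


def build_predictor_table(
    scores: DispensabilityScores,
    genes: list[GeneModel],
    te_genes: list[GeneModel],
    exon_counts: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene predictor columns for external regression modelling.

    Columns: dispensability_score, distance_to_nearest_TE, gene_length
    and (when supplied) exon_count. The regression itself is out of
    scope here; this table is its input.
    """
    distances = nearest_feature_distances(genes, te_genes)
    lengths = pd.Series({g.gene_id: g.length for g in genes}, dtype=float)
    frame = pd.DataFrame(
        {
            "dispensability_score": scores.scores,
            "distance_to_nearest_TE": distances,
            "gene_length": lengths,
        }
    )
    if exon_counts is not None:
        frame["exon_count"] = exon_counts
    frame.index.name = "gene_id"
    return frame.loc[[g.gene_id for g in genes if g.gene_id in scores.scores.index]]
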