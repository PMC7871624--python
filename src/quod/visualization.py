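"""Score visualisations: histogram, box plot, genome-wide heatmap.

Every plot also writes a TSV sidecar with the data it rendered (bin
edges and counts, box statistics, per-bin mean scores), so downstream
checks operate on numbers, never on pixels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import Normalize

from .errors import InputError, ParameterError, ValidationError
from .models import DispensabilityScores, GeneModel

# continuous low-blue to high-pink palette
SCORE_CMAP = "cool"
NEUTRAL_COLOR = "0.85"


@dataclass(frozen=True)
class ChromosomeLayout:
    """Length and optional centromere position of one reference sequence."""

    seq_id: str
    length: int
    centromere_position: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"{self.seq_id}: chromosome length must be > 0")
        if self.centromere_position is not None and not (
            1 <= self.centromere_position <= self.length
        ):
            raise ValidationError(
                f"{self.seq_id}: centromere position {self.centromere_position} "
                f"outside [1, {self.length}]"
            )


def read_chromosome_layout(path: str | os.PathLike) -> list[ChromosomeLayout]:
    """TSV with columns seq_id, length and optional centromere_position."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"chromosome layout file not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    if "seq_id" not in frame.columns or "length" not in frame.columns:
        raise ValidationError(f"{path}: need columns seq_id and length")
    layouts = []
    for _, row in frame.iterrows():
        centro = row.get("centromere_position")
        centro = None if pd.isna(centro) else int(centro)
        layouts.append(ChromosomeLayout(str(row["seq_id"]), int(row["length"]), centro))
    return layouts


def _require_finite(scores: DispensabilityScores) -> np.ndarray:
    if len(scores.scores) == 0:
        raise ParameterError("no scores to plot")
    arr = scores.scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("scores contain infinite values; cap them before plotting")
    return arr


def _sidecar(out_path: Path) -> Path:
    return out_path.with_suffix(out_path.suffix + ".tsv")


def score_histogram(
    scores: DispensabilityScores, bins: int = 100, out_path: str | os.PathLike = "histogram.png"
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of scores, bars coloured by bin midpoint, log-scaled counts.

    Bins are equal-width over [min, max]. Returns (counts, bin_edges);
    a sidecar TSV records the same.
    """
    arr = _require_finite(scores)
    out_path = Path(out_path)
    counts, edges = np.histogram(arr, bins=bins)
    mids = (edges[:-1] + edges[1:]) / 2.0
    cmap = colormaps[SCORE_CMAP]
    span = edges[-1] - edges[0]
    norm = Normalize(vmin=edges[0], vmax=edges[-1] if span > 0 else edges[0] + 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(mids, counts, width=np.diff(edges), color=cmap(norm(mids)), edgecolor="none")
    ax.set_yscale("log")
    ax.set_xlabel("dispensability score")
    ax.set_ylabel("number of genes")
    fig.tight_layout()
    try:
        fig.savefig(out_path)
    except OSError as exc:
        raise InputError(f"cannot write plot to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}).to_csv(
        _sidecar(out_path), sep="\t", index=False
    )
    return counts, edges


def score_boxplot(
    scores: DispensabilityScores, out_path: str | os.PathLike = "boxplot.png"
) -> dict[str, float]:
    """One horizontal box over all scores with median and mean marked.

    The mean is the dashed line, the median the solid one. Returns the
    box statistics that were drawn.
    """
    arr = _require_finite(scores)
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.boxplot(
        arr,
        orientation="horizontal",
        showmeans=True,
        meanline=True,
        meanprops={"linestyle": "--", "color": "tab:blue"},
        medianprops={"color": "tab:blue"},
    )
    ax.set_xlabel("dispensability score")
    ax.set_yticks([])
    fig.tight_layout()
    try:
        fig.savefig(out_path)
    except OSError as exc:
        raise InputError(f"cannot write plot to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    result = {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
        "n": float(len(arr)),
    }
    pd.DataFrame([result]).to_csv(_sidecar(out_path), sep="\t", index=False)
    return result


def bin_scores_by_position(
    scores: DispensabilityScores,
    genes: list[GeneModel],
    layout: list[ChromosomeLayout],
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Mean score per fixed-width genomic bin of gene midpoints.

    Bins are half-open [i*bin_size, (i+1)*bin_size); a midpoint exactly
    on a boundary falls into the right-hand bin. Empty bins have NaN.
    """
    if bin_size <= 0:
        raise ParameterError("bin_size must be > 0")
    known = {lay.seq_id: lay for lay in layout}
    unknown = sorted({g.seq_id for g in genes} - set(known))
    if unknown:
        raise ValidationError(f"genes on sequences absent from layout: {unknown}")
    rows = []
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    for gene in genes:
        if gene.gene_id not in scores.scores.index:
            continue
        idx = int(gene.midpoint // bin_size)
        key = (gene.seq_id, idx)
        sums[key] = sums.get(key, 0.0) + float(scores.scores[gene.gene_id])
        counts[key] = counts.get(key, 0) + 1
    for lay in layout:
        n_bins = int(np.ceil(lay.length / bin_size))
        for i in range(n_bins):
            key = (lay.seq_id, i)
            n = counts.get(key, 0)
            rows.append(
                {
                    "seq_id": lay.seq_id,
                    "bin_start": i * bin_size,
                    "bin_end": min((i + 1) * bin_size, lay.length),
                    "n_genes": n,
                    "mean_score": sums[key] / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def genome_wide_score_heatmap(
    scores: DispensabilityScores,
    genes: list[GeneModel],
    layout: list[ChromosomeLayout],
    bin_size: int = 100_000,
    out_path: str | os.PathLike = "heatmap.png",
) -> pd.DataFrame:
    """Per-chromosome score heatmap with optional centromere marks.

    One horizontal track per chromosome; bin colour is the mean score of
    the genes whose midpoints fall into the bin, empty bins neutral
    grey, centromeres black dots, x-axis in Mbp. Returns (and writes as
    sidecar) the binned table.
    """
    _require_finite(scores)
    out_path = Path(out_path)
    table = bin_scores_by_position(scores, genes, layout, bin_size=bin_size)
    finite = table["mean_score"].dropna()
    vmin = float(finite.min()) if len(finite) else 0.0
    vmax = float(finite.max()) if len(finite) else 1.0
    if vmax == vmin:
        vmax = vmin + 1.0
    cmap = colormaps[SCORE_CMAP].copy()
    cmap.set_bad(NEUTRAL_COLOR)
    norm = Normalize(vmin=vmin, vmax=vmax)

    fig, axes = plt.subplots(
        len(layout), 1, figsize=(10, 0.9 * len(layout) + 1.2), sharex=True, squeeze=False
    )
    for ax, lay in zip(axes[:, 0], layout):
        sub = table[table["seq_id"] == lay.seq_id]
        values = np.ma.masked_invalid(sub["mean_score"].to_numpy(dtype=float))
        extent = (0.0, lay.length / 1e6, 0.0, 1.0)
        ax.imshow(
            values[np.newaxis, :],
            aspect="auto",
            cmap=cmap,
            norm=norm,
            extent=extent,
            interpolation="nearest",
        )
        if lay.centromere_position is not None:
            ax.plot(lay.centromere_position / 1e6, 0.5, "ko", markersize=6)
        ax.set_yticks([])
        ax.set_ylabel(lay.seq_id, rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("position [Mbp]")
    fig.colorbar(
        plt.cm.ScalarMappable(norm=norm, cmap=cmap),
        ax=axes[:, 0],
        label="mean dispensability score",
    )
    try:
        fig.savefig(out_path)
    except OSError as exc:
        raise InputError(f"cannot write plot to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    table.to_csv(_sidecar(out_path), sep="\t", index=False)
    return table
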