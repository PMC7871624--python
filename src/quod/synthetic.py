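"""Synthetic pangenome data with known presence/absence and copy-number truth.

The generator emulates the statistical structure the dispensability
score assumes: genomes differ in sequencing depth, some genes are absent
from a configurable fraction of genomes (PAV), some vary in copy number
(CNV), and per-gene coverage carries multiplicative lognormal noise. A
closed-form oracle evaluates the score equation directly on the
noise-free expected coverages, independently of the scoring module, and
a fixture writer realises small specs as reference FASTA + GFF3 + one
SAM per genome with exact integer read depths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .models import CoverageMatrix, DispensabilityScores


@dataclass
class PangenomeSpec:
    """Parameters of a simulated pangenome coverage experiment.

    ``pav_genes`` maps gene index -> absence fraction f in [0, 1): each
    genome independently lacks the gene with probability f.
    ``cnv_genes`` maps gene index -> copy-number multiplier applied in
    every genome carrying the gene. ``depth_per_genome`` is the mean
    sequencing depth of each genome; ``noise_cv`` the coefficient of
    variation of the multiplicative lognormal coverage noise.
    """

    n_genes: int
    n_genomes: int
    gene_length: int = 1_000
    pav_genes: dict[int, float] = field(default_factory=dict)
    cnv_genes: dict[int, float] = field(default_factory=dict)
    depth_per_genome: list[float] | None = None
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_genomes < 1:
            raise ParameterError("need at least one gene and one genome")
        if self.gene_length < 1:
            raise ParameterError("gene_length must be >= 1")
        if self.depth_per_genome is None:
            self.depth_per_genome = [20.0] * self.n_genomes
        if len(self.depth_per_genome) != self.n_genomes:
            raise ParameterError(
                f"depth_per_genome has {len(self.depth_per_genome)} entries "
                f"for {self.n_genomes} genomes"
            )
        if any(d <= 0 for d in self.depth_per_genome):
            raise ParameterError("all sequencing depths must be > 0")
        for idx, f in self.pav_genes.items():
            if not 0 <= idx < self.n_genes:
                raise ParameterError(f"PAV gene index {idx} out of range")
            if not 0.0 <= f < 1.0:
                raise ParameterError(f"absence fraction {f} for gene {idx} not in [0, 1)")
        for idx, c in self.cnv_genes.items():
            if not 0 <= idx < self.n_genes:
                raise ParameterError(f"CNV gene index {idx} out of range")
            if c < 0:
                raise ParameterError(f"copy number {c} for gene {idx} must be >= 0")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def genome_ids(self) -> list[str]:
        width = len(str(self.n_genomes - 1))
        return [f"genome{j:0{width}d}" for j in range(self.n_genomes)]


@dataclass
class TruthTable:
    """Ground-truth presence and copy number behind a simulated matrix."""

    presence: pd.DataFrame  # genes x genomes, {0, 1}
    copy_number: pd.DataFrame  # genes x genomes, >= 0; 0 wherever absent

    def __post_init__(self) -> None:
        pres = self.presence.to_numpy()
        copy = self.copy_number.to_numpy()
        if not np.isin(pres, (0, 1)).all():
            raise ParameterError("presence entries must be 0 or 1")
        if (copy < 0).any() or ((pres == 0) & (copy != 0)).any():
            raise ParameterError("copy_number must be >= 0 and 0 wherever absent")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    # lognormal with E[X] = 1 and SD[X]/E[X] = cv
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_coverage_matrix(spec: PangenomeSpec) -> tuple[CoverageMatrix, TruthTable]:
    """Draw a coverage matrix under ``spec``; reproducible for a fixed seed.

    coverage(g, n) = depth_n * copy(g) * presence(g, n) * noise(g, n),
    with one independent RNG stream per genome so the draw for genome j
    does not depend on how many other genomes exist.
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(spec.n_genomes)]
    presence = np.ones((spec.n_genes, spec.n_genomes), dtype=int)
    copy = np.ones((spec.n_genes, spec.n_genomes), dtype=float)
    coverage = np.empty((spec.n_genes, spec.n_genomes), dtype=float)
    base_copy = np.ones(spec.n_genes, dtype=float)
    for idx, mult in spec.cnv_genes.items():
        base_copy[idx] = mult
    for j, rng in enumerate(streams):
        for idx, f in spec.pav_genes.items():
            if rng.random() < f:
                presence[idx, j] = 0
        copy[:, j] = base_copy * presence[:, j]
        noise = (
            _lognormal_unit_mean(rng, spec.noise_cv, spec.n_genes)
            if spec.noise_cv > 0
            else np.ones(spec.n_genes)
        )
        coverage[:, j] = spec.depth_per_genome[j] * copy[:, j] * noise
    gene_idx = pd.Index(spec.gene_ids, name="gene_id")
    matrix = CoverageMatrix(pd.DataFrame(coverage, index=gene_idx, columns=spec.genome_ids))
    truth = TruthTable(
        presence=pd.DataFrame(presence, index=gene_idx, columns=spec.genome_ids),
        copy_number=pd.DataFrame(copy, index=gene_idx, columns=spec.genome_ids),
    )
    return matrix, truth


def expected_scores_oracle(truth: TruthTable, spec: PangenomeSpec) -> DispensabilityScores:
    """Closed-form scores from the noise-free expected coverages.

    A literal, loop-level transcription of the score equation applied to
    depth * copy_number; deliberately independent of the scoring module
    so the two code paths can check each other.
    """
    genes = list(truth.presence.index)
    genomes = list(truth.presence.columns)
    expected = {
        n: {g: spec.depth_per_genome[j] * float(truth.copy_number.at[g, n]) for g in genes}
        for j, n in enumerate(genomes)
    }
    genic_mean = {n: sum(expected[n][g] for g in genes) / len(genes) for n in genomes}
    scores = {}
    big_n = len(genomes)
    for g in genes:
        total = 0.0
        for n in genomes:
            total += expected[n][g] / genic_mean[n]
        mean_norm = total / big_n
        scores[g] = (1.0 / mean_norm) if mean_norm > 0 else float("inf")
    return DispensabilityScores(
        scores=pd.Series(scores, name="dispensability_score").loc[genes],
        n_genomes_used=big_n,
    )


_SPACER = 200  # bp of non-genic sequence between and around genes


def _reference_layout(spec: PangenomeSpec) -> list[tuple[str, int, int]]:
    """(gene_id, start, end) 1-based inclusive positions on one sequence."""
    layout = []
    pos = _SPACER + 1
    for gene_id in spec.gene_ids:
        layout.append((gene_id, pos, pos + spec.gene_length - 1))
        pos += spec.gene_length + _SPACER
    return layout


def emit_alignment_fixture(spec: PangenomeSpec, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Realise a noise-free spec as FASTA + GFF3 + one SAM per genome.

    Genes are laid out on a single reference sequence separated by
    spacers. Each present gene in genome n receives exactly
    round(depth_n * copy) full-length, perfectly aligned primary reads
    (flag 0, MAPQ 60, CIGAR '<L>M'), so its computed coverage equals
    that integer exactly. Requires ``noise_cv == 0`` and integer
    effective depths. Returns paths keyed by 'fasta', 'gff', 'truth' and
    each genome id.
    """
    if spec.noise_cv != 0:
        raise ParameterError("alignment fixtures require noise_cv == 0 (exact depths)")
    if spec.n_genes * spec.gene_length > 1_000_000:
        raise ParameterError("fixture reference would exceed 1 Mbp of genic sequence")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create fixture directory {out_dir}: {exc}") from exc

    layout = _reference_layout(spec)
    ref_len = layout[-1][2] + _SPACER
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(rng.choice(list("ACGT"), size=ref_len))
    seq_id = "chr1"

    paths: dict[str, Path] = {}
    fasta_path = out_dir / "reference.fasta"
    with open(fasta_path, "w") as handle:
        handle.write(f">{seq_id}\n")
        for i in range(0, ref_len, 60):
            handle.write(sequence[i : i + 60] + "\n")
    paths["fasta"] = fasta_path

    gff_path = out_dir / "annotation.gff3"
    with open(gff_path, "w") as handle:
        handle.write("##gff-version 3\n")
        handle.write(f"##sequence-region {seq_id} 1 {ref_len}\n")
        for gene_id, start, end in layout:
            handle.write(
                f"{seq_id}\tquod_fixture\tgene\t{start}\t{end}\t.\t+\t.\tID={gene_id}\n"
            )
    paths["gff"] = gff_path

    _, truth = simulate_coverage_matrix(spec)
    truth_path = out_dir / "truth.tsv"
    truth_frame = pd.concat(
        {"presence": truth.presence, "copy_number": truth.copy_number}, axis=1
    )
    truth_frame.to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path

    starts = {gene_id: start for gene_id, start, _ in layout}
    length = spec.gene_length
    for j, genome_id in enumerate(spec.genome_ids):
        sam_path = out_dir / f"{genome_id}.sam"
        with open(sam_path, "w") as handle:
            handle.write("@HD\tVN:1.6\tSO:coordinate\n")
            handle.write(f"@SQ\tSN:{seq_id}\tLN:{ref_len}\n")
            for gene_id in spec.gene_ids:
                copies = float(truth.copy_number.at[gene_id, genome_id])
                depth = spec.depth_per_genome[j] * copies
                n_reads = int(round(depth))
                if abs(depth - n_reads) > 1e-9:
                    raise ParameterError(
                        f"effective depth {depth} for {gene_id} in {genome_id} is not an integer"
                    )
                start = starts[gene_id]
                read_seq = sequence[start - 1 : start - 1 + length]
                for k in range(n_reads):
                    handle.write(
                        f"{gene_id}.read{k}\t0\t{seq_id}\t{start}\t60\t{length}M\t*\t0\t0\t"
                        f"{read_seq}\t{'I' * length}\n"
                    )
        paths[genome_id] = sam_path
    return paths
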