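"""Annotation and alignment input, coverage computation, matrix persistence.

Coverage of a gene is the average read depth over its full feature span:
the sum, over every reference position in the span, of the number of
retained alignments whose CIGAR consumes that position, divided by the
gene length. Unmapped, secondary and supplementary records are excluded;
duplicates are counted; a MAPQ threshold is available but off by default.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .errors import InputError, ParseError, ValidationError
from .models import CoverageMatrix, GeneModel, GenomeCoverageProfile

# CIGAR operations whose span covers reference positions: M, D, =, X.
# N (intron skip) consumes reference but leaves it uncovered; I/S/H/P
# consume no reference at all.
_COVERING_OPS = {0, 2, 7, 8}
_REF_CONSUMING_OPS = {0, 2, 3, 7, 8}


def parse_gene_annotation(gff_path: str | os.PathLike, feature_type: str = "gene") -> list[GeneModel]:
    """Read GFF3 features of ``feature_type`` into :class:`GeneModel` objects.

    Features are returned in file order with 1-based inclusive coordinates
    as stored in the GFF3. Every kept feature must carry an ``ID``
    attribute; an empty result is an error, never a silent empty list.
    """
    path = Path(gff_path)
    if not path.is_file():
        raise InputError(f"annotation file not found: {path}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise ParseError(f"{path}:{lineno}: not a 9-column GFF3 line")
            feature = feature_from_line(line)
            if feature.featuretype != feature_type:
                continue
            ids = feature.attributes.get("ID")
            if not ids:
                raise ParseError(f"{path}:{lineno}: {feature_type} feature without an ID attribute")
            gene_id = ids[0]
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            strand = feature.strand if feature.strand in {"+", "-"} else "."
            genes.append(GeneModel(gene_id, feature.seqid, feature.start, feature.end, strand))
    if not genes:
        raise ValidationError(f"no genes found: no {feature_type!r} features in {path}")
    return genes


def count_exons(gff_path: str | os.PathLike, genes: list[GeneModel]) -> pd.Series:
    """Count exon features per gene by matching exon spans to gene spans.

    Exons are attributed to the gene whose span contains them on the same
    reference sequence (ties go to the first gene in annotation order).
    Genes without exon features get a count of 0.
    """
    path = Path(gff_path)
    if not path.is_file():
        raise InputError(f"annotation file not found: {path}")
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.seq_id, IntervalTree())[gene.start : gene.end + 1] = gene.gene_id
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=int)
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            seqid, start, end = fields[0], int(fields[3]), int(fields[4])
            tree = trees.get(seqid)
            if tree is None:
                continue
            hits = sorted(tree[start : end + 1], key=lambda iv: iv.begin)
            if hits:
                counts[hits[0].data] += 1
    return counts


def _covering_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Half-open 0-based reference intervals covered by a record's CIGAR."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in _COVERING_OPS:
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
        if op in _REF_CONSUMING_OPS:
            pos += length
    return blocks


def compute_gene_coverage(
    alignment_path: str | os.PathLike,
    genes: list[GeneModel],
    min_mapq: int = 0,
    genome_id: str | None = None,
) -> GenomeCoverageProfile:
    """Mean read depth per gene from one SAM/BAM file.

    Streams every record once (no index required); per gene, the aligned
    reference overlap of each retained record with the gene span is
    accumulated and divided by the gene length. Unmapped, secondary and
    supplementary records are skipped; records below ``min_mapq`` are
    skipped; duplicates are counted.
    """
    path = Path(alignment_path)
    if not path.is_file():
        raise InputError(f"alignment file not found: {path}")
    if genome_id is None:
        genome_id = path.name.rsplit(".", 1)[0]
    if not genes:
        raise ValidationError("empty gene list")

    covered_bases = {g.gene_id: 0.0 for g in genes}
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # store 0-based half-open spans
        trees.setdefault(gene.seq_id, IntervalTree())[gene.start - 1 : gene.end] = gene.gene_id

    with pysam.AlignmentFile(str(path), require_index=False) as aln:
        header_refs = set(aln.references)
        missing = sorted({g.seq_id for g in genes} - header_refs)
        if missing:
            raise ValidationError(
                f"gene reference sequences absent from alignment header of {path.name}: {missing}"
            )
        for read in aln.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            for block_start, block_end in _covering_blocks(read):
                for iv in tree[block_start:block_end]:
                    overlap = min(block_end, iv.end) - max(block_start, iv.begin)
                    if overlap > 0:
                        covered_bases[iv.data] += overlap

    coverage = pd.Series(
        {g.gene_id: covered_bases[g.gene_id] / g.length for g in genes}, dtype=float
    )
    # preserve annotation order
    coverage = coverage.loc[[g.gene_id for g in genes]]
    return GenomeCoverageProfile(genome_id=genome_id, per_gene_coverage=coverage)


def assemble_coverage_matrix(profiles: list[GenomeCoverageProfile]) -> CoverageMatrix:
    """Stack per-genome profiles into a genes × genomes matrix.

    Rows follow the gene order of the first profile; columns follow input
    order. All profiles must cover an identical gene set.
    """
    if not profiles:
        raise ValidationError("no coverage profiles supplied")
    genome_ids = [p.genome_id for p in profiles]
    if len(set(genome_ids)) != len(genome_ids):
        dup = sorted({g for g in genome_ids if genome_ids.count(g) > 1})
        raise ValidationError(f"duplicate genome ids: {dup}")
    reference_genes = list(profiles[0].per_gene_coverage.index)
    ref_set = set(reference_genes)
    for profile in profiles[1:]:
        other = set(profile.per_gene_coverage.index)
        if other != ref_set:
            diff = sorted(ref_set.symmetric_difference(other))
            raise ValidationError(
                f"gene sets differ between profiles (symmetric difference: {diff})"
            )
    data = {p.genome_id: p.per_gene_coverage.loc[reference_genes] for p in profiles}
    frame = pd.DataFrame(data, index=pd.Index(reference_genes, name="gene_id"))
    return CoverageMatrix(frame)


_GENIC_MEANS_TAG = "#genic_means"


def write_coverage_matrix(matrix: CoverageMatrix, path: str | os.PathLike) -> Path:
    """Persist a coverage matrix as TSV at full floating precision.

    Layout: one comment line recording the per-genome genic means, then a
    header row of genome ids with ``gene_id`` as the first column.
    """
    path = Path(path)
    if matrix.n_genes == 0:
        raise ValidationError("refusing to write an empty coverage matrix")
    try:
        with open(path, "w") as handle:
            means = "\t".join(repr(float(v)) for v in matrix.genic_means)
            handle.write(f"{_GENIC_MEANS_TAG}\t{means}\n")
            handle.write("gene_id\t" + "\t".join(matrix.genome_ids) + "\n")
            for gene_id, row in matrix.values.iterrows():
                handle.write(gene_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write coverage matrix to {path}: {exc}") from exc
    return path


def read_coverage_matrix(path: str | os.PathLike) -> CoverageMatrix:
    """Read a TSV coverage matrix written by :func:`write_coverage_matrix`.

    The genic-means comment line is optional; genic means are always
    recomputed from the values. Ragged rows, negative entries and
    duplicated labels are rejected.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"coverage matrix file not found: {path}")
    with open(path) as handle:
        first = handle.readline()
        skip = 1 if first.startswith(_GENIC_MEANS_TAG) else 0
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            skiprows=skip,
            index_col=0,
            dtype=str,
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed coverage matrix {path}: {exc}") from exc
    if frame.isna().any().any():
        raise ValidationError(f"ragged or incomplete rows in coverage matrix {path}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric entry in coverage matrix {path}: {exc}") from exc
    frame.index.name = "gene_id"
    return CoverageMatrix(frame)
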