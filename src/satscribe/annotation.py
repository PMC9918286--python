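"""Genomic-context classification of satellites.

Each satellite gets exactly one location class — exon, intron or
intergenic — against a set of gene models (priority exon > intron >
intergenic, any >= 1 nt overlap counts), plus the labels of any
transposon/repeat annotation intervals (e.g. Helitron catalogue entries)
it overlaps.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .records import GeneModel, RepeatAnnotation, SatelliteRecord

LOCATION_CLASSES = ("intergenic", "intron", "exon")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3/GTF ``gene`` and ``exon`` records.

    Exons of all transcripts of a gene are pooled (union per gene); other
    feature types are ignored.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = []
        for e in db.children(g, featuretype="exon"):
            exons.append((e.start - 1, e.end))  # GFF is 1-based inclusive
        exons.sort()
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons,
            )
        )
    return genes


class _GeneIndex:
    def __init__(self, genes: list[GeneModel]) -> None:
        self.gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            self.gene_trees[g.chrom].addi(g.start, g.end, g.gene_id)
            for s, e in g.exons:
                self.exon_trees[g.chrom].addi(s, e, g.gene_id)


def classify_location(
    sat: SatelliteRecord,
    genes: list[GeneModel] | _GeneIndex,
) -> str:
    """Classify one satellite as exon / intron / intergenic.

    Exon wins over intron wins over intergenic; overlap of a single
    nucleotide is enough.  A chromosome absent from the annotation is
    classified intergenic with a warning.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    if sat.chrom not in index.gene_trees:
        warnings.warn(
            f"chromosome {sat.chrom!r} absent from gene annotation; "
            f"classifying {sat.id} as intergenic",
            stacklevel=2,
        )
        return "intergenic"
    if index.exon_trees[sat.chrom].overlap(sat.start, sat.end):
        return "exon"
    if index.gene_trees[sat.chrom].overlap(sat.start, sat.end):
        return "intron"
    return "intergenic"


def overlap_repeat_annotation(
    sat: SatelliteRecord,
    repeats: list[RepeatAnnotation] | dict[str, IntervalTree],
) -> list[str]:
    """Labels of every annotation interval overlapping the satellite >= 1 nt."""
    if isinstance(repeats, dict):
        trees = repeats
    else:
        trees = build_repeat_index(repeats)
    if sat.chrom not in trees:
        return []
    hits = trees[sat.chrom].overlap(sat.start, sat.end)
    return sorted({iv.data for iv in hits})


def build_repeat_index(repeats: list[RepeatAnnotation]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in repeats:
        trees[r.chrom].addi(r.start, r.end, r.label)
    return dict(trees)


def annotate_satellites(
    records: list[SatelliteRecord],
    genes: list[GeneModel],
    repeats: list[RepeatAnnotation] | None = None,
) -> list[SatelliteRecord]:
    """Attach location class and repeat labels to every record, in place."""
    index = _GeneIndex(genes)
    repeat_index = build_repeat_index(repeats or [])
    for rec in records:
        rec.location = classify_location(rec, index)
        rec.repeat_labels = overlap_repeat_annotation(rec, repeat_index)
    return records
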