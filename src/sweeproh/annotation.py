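"""Candidate-region annotation: gene overlap, known/novel status, QTL traits.

Candidate intervals (sweep regions or conserved-ROH regions) are joined to
gene features from a GTF and to QTL intervals from a tab-separated catalogue
in the style of a livestock QTL-database export. All interval arithmetic is
on 1-based inclusive coordinates (the native convention of both GTF and the
QTL export); BED conversion happens only at file boundaries.

A region is retained when at least one gene overlaps it by
``min_overlap_bp`` (default 50 kb). A gene hit is *novel* when the gene
record carries a stable ``gene_id`` but no ``gene_name`` — the operational
signature of an uncharacterized locus in a reference annotation release.

QTL overlap uses a 1 bp threshold. Overlapping records are deduplicated
first by QTL identifier, then reduced to the set of unique trait names,
which are counted per trait class under the six-class livestock trait
hierarchy (health, meat and carcass, milk, production, reproduction,
exterior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

TRAIT_CLASSES = (
    "health",
    "meat and carcass",
    "milk",
    "production",
    "reproduction",
    "exterior",
)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GeneFeature:
    chromosome: str
    start: int
    end: int
    gene_id: str
    gene_name: str | None = None
    biotype: str = ""

    @property
    def is_novel(self) -> bool:
        return self.gene_name is None


@dataclass(frozen=True)
class RegionGeneHit:
    region: object            # any object with .chromosome/.start/.end
    gene: GeneFeature
    overlap_bp: int
    status: str               # "known" | "novel"


@dataclass(frozen=True)
class QtlRecord:
    chromosome: str
    start: int
    end: int
    qtl_id: str
    trait_name: str
    trait_class: str


def read_gtf(path: str) -> list[GeneFeature]:
    """Parse ``gene`` features from a GTF; other feature types are ignored.

    ``gene_id`` is required (features without it are skipped with a
    warning); ``gene_name`` is optional and its absence marks the gene
    novel downstream.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneFeature] = []
    skipped = 0
    for f in db.features_of_type("gene"):
        gene_ids = f.attributes.get("gene_id")
        if not gene_ids or not gene_ids[0]:
            skipped += 1
            continue
        names = f.attributes.get("gene_name")
        biotypes = f.attributes.get("gene_biotype") or f.attributes.get("biotype")
        genes.append(
            GeneFeature(
                chromosome=f.seqid,
                start=int(f.start),
                end=int(f.end),
                gene_id=gene_ids[0],
                gene_name=names[0] if names else None,
                biotype=biotypes[0] if biotypes else "",
            )
        )
    if skipped:
        logger.warning("read_gtf: skipped %d gene features lacking gene_id", skipped)
    return genes


def overlap_1based(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _tree_by_chrom(items: Iterable, get) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for it in items:
        chrom, start, end = get(it)
        # IntervalTree is half-open; store [start, end+1) for inclusive ends
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, it)
    return trees


def annotate_regions(
    regions: Sequence,
    genes: Sequence[GeneFeature],
    min_overlap_bp: int = 50_000,
) -> list[RegionGeneHit]:
    """Join regions to genes; keep hits overlapping >= ``min_overlap_bp``.

    Regions with no qualifying gene are dropped (they simply produce no
    hits). Each hit is classified known/novel from the gene's name status.
    """
    if not genes:
        logger.warning("annotate_regions: empty gene annotation; all regions dropped")
        return []
    trees = _tree_by_chrom(genes, lambda g: (g.chromosome, g.start, g.end))
    hits: list[RegionGeneHit] = []
    for region in regions:
        tree = trees.get(region.chromosome)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(region.start, region.end + 1)):
            gene = iv.data
            ov = overlap_1based(region.start, region.end, gene.start, gene.end)
            if ov >= min_overlap_bp:
                hits.append(
                    RegionGeneHit(
                        region=region,
                        gene=gene,
                        overlap_bp=ov,
                        status="novel" if gene.is_novel else "known",
                    )
                )
    return hits


def gene_set_intersections(
    per_population: dict[str, set[str]],
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-population unique gene sets and the common intersection.

    ``unique[p]`` holds genes found in population *p* and in no other;
    ``common`` is the intersection across all populations.
    """
    if len(per_population) < 2:
        raise ValueError("need at least 2 populations")
    labels = list(per_population)
    common = set.intersection(*(set(per_population[p]) for p in labels))
    unique: dict[str, set[str]] = {}
    for p in labels:
        others = set().union(*(per_population[q] for q in labels if q != p))
        unique[p] = set(per_population[p]) - others
    return unique, common


def read_qtl_table(path: str, trait_class_map: dict[str, str] | None = None) -> list[QtlRecord]:
    """Read a tab-separated QTL catalogue (chrom, start, end, qtl_id,
    trait_name, trait_class; 1-based inclusive).

    Records whose ``trait_class`` is not one of the six hierarchy classes
    are remapped through ``trait_class_map`` (trait name -> class) when
    provided; still-unmappable records are flagged ``unclassified``.
    Malformed rows are skipped with a warning. Duplicate QTL identifiers
    are kept — deduplication happens in the overlap summary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chrom", "start", "end", "qtl_id", "trait_name", "trait_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"QTL table missing columns: {missing}")
    records: list[QtlRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            skipped += 1
            continue
        raw_class = row.trait_class if isinstance(row.trait_class, str) else ""
        klass = raw_class.strip().lower()
        if klass not in TRAIT_CLASSES:
            mapped = (trait_class_map or {}).get(row.trait_name)
            klass = mapped if mapped in TRAIT_CLASSES else UNCLASSIFIED
        records.append(
            QtlRecord(
                chromosome=str(row.chrom),
                start=start,
                end=end,
                qtl_id=str(row.qtl_id),
                trait_name=str(row.trait_name),
                trait_class=klass,
            )
        )
    if skipped:
        logger.warning("read_qtl_table: skipped %d malformed rows", skipped)
    return records


def read_trait_class_map(path: str) -> dict[str, str]:
    """Read a two-column (trait_name, trait_class) tab-separated mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].str.lower()))


def dedup_qtl(records: Sequence[QtlRecord]) -> tuple[list[QtlRecord], set[str]]:
    """Deduplicate by qtl_id (first occurrence wins), then reduce to the
    unique trait-name set. Idempotent. Returns (unique-id records, names)."""
    seen: dict[str, QtlRecord] = {}
    for r in records:
        seen.setdefault(r.qtl_id, r)
    unique_records = list(seen.values())
    names = {r.trait_name for r in unique_records}
    return unique_records, names


def qtl_overlap_summary(regions: Sequence, qtls: Sequence[QtlRecord]) -> dict:
    """Overlap QTL records with regions (>= 1 bp), dedup, count per class.

    Returns a dict with the overlapping raw record count, unique QTL-id
    count, unique trait-name count, and per-class counts of unique trait
    names (a trait name's class is taken from its first unique-id record).
    """
    trees = _tree_by_chrom(qtls, lambda q: (q.chromosome, q.start, q.end))
    overlapping: list[QtlRecord] = []
    seen_ids: set[tuple] = set()
    for region in regions:
        tree = trees.get(region.chromosome)
        if tree is None:
            continue
        for iv in tree.overlap(region.start, region.end + 1):
            q = iv.data
            key = (q.qtl_id, q.chromosome, q.start, q.end, q.trait_name)
            if key not in seen_ids:
                seen_ids.add(key)
                overlapping.append(q)
    unique_records, names = dedup_qtl(overlapping)
    class_counts = {c: 0 for c in TRAIT_CLASSES}
    class_counts[UNCLASSIFIED] = 0
    counted: set[str] = set()
    for r in unique_records:
        if r.trait_name in counted:
            continue
        counted.add(r.trait_name)
        class_counts[r.trait_class] += 1
    return {
        "raw_overlapping_records": len(overlapping),
        "unique_qtl_ids": len(unique_records),
        "unique_trait_names": len(names),
        "class_counts": class_counts,
    }
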