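"""Interval logic linking sRNA clusters to genes and calling physical
same-annotation gene clusters.

An sRNA cluster is linked to every protein-coding gene whose body extended by
``flank_window`` base pairs on each side (default 2,500 bp, clipped at 0)
intersects the cluster, using 0-based half-open arithmetic on the same
chromosome. The window is symmetric and strand-agnostic (`bedtools window`
semantics); strand only informs the reported upstream/downstream label.

Physical gene clusters are maximal runs of >= ``min_cluster_genes`` genes
sharing an annotation label in which consecutive genes (sorted by start,
per chromosome and label) are separated by an end-to-start gap of at most
``gap_threshold`` bp (default 5,000).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneFeature, SrnaCluster

__all__ = [
    "WindowParams",
    "SrnaGeneLink",
    "GeneClusterCall",
    "assign_clusters_to_genes",
    "links_to_frame",
    "srna_size_class",
    "call_gene_clusters",
    "gene_clusters_to_frame",
]


@dataclass(frozen=True)
class WindowParams:
    flank_window: int = 2500
    gap_threshold: int = 5000
    min_cluster_genes: int = 3

    def __post_init__(self) -> None:
        if self.flank_window <= 0 or self.gap_threshold <= 0 or self.min_cluster_genes <= 0:
            raise ValueError("all window parameters must be positive")


@dataclass(frozen=True)
class SrnaGeneLink:
    """One (cluster, gene) assignment. distance is 0 for clusters overlapping
    the gene body, else the bp gap between cluster and gene body."""

    cluster_id: str
    gene_id: str
    distance: int
    position: str  # upstream | overlapping | downstream


@dataclass(frozen=True)
class GeneClusterCall:
    cluster_label: str
    annotation_label: str
    gene_ids: tuple[str, ...]
    chrom: str
    span: int


def _position(cluster: SrnaCluster, gene: GeneFeature) -> tuple[int, str]:
    if cluster.end <= gene.start:
        distance = gene.start - cluster.end
        before = True
    elif cluster.start >= gene.end:
        distance = cluster.start - gene.end
        before = False
    else:
        return 0, "overlapping"
    if gene.strand == "-":
        return distance, "downstream" if before else "upstream"
    return distance, "upstream" if before else "downstream"


def assign_clusters_to_genes(
    clusters: list[SrnaCluster],
    genes: list[GeneFeature],
    w: WindowParams = WindowParams(),
) -> list[SrnaGeneLink]:
    """Link each sRNA cluster to all protein-coding genes whose flanked body
    it intersects; a cluster near several genes yields several links, and
    unlinked clusters simply contribute no rows."""
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dup: set[str] = set()
        for gid in gene_ids:
            (dup if gid in seen else seen).add(gid)
        raise ValueError(f"duplicate gene ids: {sorted(dup)}")

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    eligible = {}
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        eligible[g.gene_id] = g
        trees[g.chrom].addi(max(0, g.start - w.flank_window), g.end + w.flank_window, g.gene_id)

    links: list[SrnaGeneLink] = []
    for c in sorted(clusters):
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.overlap(c.start, c.end))
        for gid in hits:
            gene = eligible[gid]
            distance, position = _position(c, gene)
            links.append(SrnaGeneLink(c.cluster_id, gid, distance, position))
    return links


def links_to_frame(links: list[SrnaGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.cluster_id, l.gene_id, l.distance, l.position) for l in links],
        columns=["cluster_id", "gene_id", "distance", "position"],
    )


def srna_size_class(cluster: SrnaCluster) -> str:
    """Size class of a cluster: 'miRNA' (flag precedence), 'nt21_22',
    'nt24', or 'other'."""
    if cluster.dicer_call == "miRNA" or cluster.rna_class == "miRNA_annotated":
        return "miRNA"
    if cluster.dicer_call in ("21", "22"):
        return "nt21_22"
    if cluster.dicer_call == "24":
        return "nt24"
    return "other"


def call_gene_clusters(
    genes: list[GeneFeature], w: WindowParams = WindowParams()
) -> list[GeneClusterCall]:
    """Chain same-annotation genes into physical clusters.

    Per (chromosome, annotation label), genes are sorted by start and chained
    while next.start - prev.end <= gap_threshold; maximal runs with at least
    ``min_cluster_genes`` members are emitted. Input order is irrelevant.
    """
    by_key: dict[tuple[str, str], list[GeneFeature]] = defaultdict(list)
    for g in genes:
        if g.annotation_label:
            by_key[(g.chrom, g.annotation_label)].append(g)

    calls: list[GeneClusterCall] = []
    for (chrom, label) in sorted(by_key):
        members = sorted(by_key[(chrom, label)], key=lambda g: (g.start, g.gene_id))
        run: list[GeneFeature] = []
        for g in members:
            if run and g.start - run[-1].end > w.gap_threshold:
                if len(run) >= w.min_cluster_genes:
                    calls.append(_make_call(label, chrom, run, len(calls)))
                run = []
            run.append(g)
        if len(run) >= w.min_cluster_genes:
            calls.append(_make_call(label, chrom, run, len(calls)))
    return calls


def _make_call(
    label: str, chrom: str, run: list[GeneFeature], ordinal: int
) -> GeneClusterCall:
    return GeneClusterCall(
        cluster_label=f"GC{ordinal + 1:04d}_{label}",
        annotation_label=label,
        gene_ids=tuple(g.gene_id for g in run),
        chrom=chrom,
        span=run[-1].end - run[0].start,
    )


def gene_clusters_to_frame(calls: list[GeneClusterCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.cluster_label, c.annotation_label, ",".join(c.gene_ids), c.chrom,
             len(c.gene_ids), c.span)
            for c in calls
        ],
        columns=["cluster_label", "annotation_label", "gene_ids", "chrom",
                 "n_genes", "span"],
    )
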