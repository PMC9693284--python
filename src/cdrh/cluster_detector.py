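"""Physical clustering of CDRHs on assigned chromosomes.

A gene cluster is a maximal run of at least two CDRHs on one chromosome
whose overall span (start of the first member to end of the last,
inclusive) stays within 200 kb. Detection is a single greedy left-to-right
pass per chromosome over ALL CDRHs regardless of class, and each cluster
is typed afterwards: homogeneous (GC_NLR / GC_RLK / GC_RLP, all members
one RGA class) or heterogeneous (GC_H). The single-pass-then-type design
keeps the homogeneous and heterogeneous counts disjoint; separate
per-class passes would double-count mixed neighbourhoods.

The observed membership range in this kind of survey is 2-8 genes, but
membership is not capped: a cluster larger than 8 raises a logged notice
rather than an arbitrary split. Clusters are disjoint (each gene belongs
to at most one), and emitted clusters are maximal: the nearest flanking
CDRH on either side would break the span constraint. Strand is ignored.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .model import ClusterType, GeneCluster, RGAClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster-detection parameters.

    max_span: maximal cluster extent in bp, first start to last end
        inclusive (default 200,000).
    min_members: minimal member count (default 2).
    notice_members: membership above which a notice is logged (default 8,
        the top of the range typically observed).
    """

    max_span: int = 200_000
    min_members: int = 2
    notice_members: Optional[int] = 8

    def __post_init__(self) -> None:
        if self.max_span <= 0:
            raise ValueError("max_span must be > 0")
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")


DEFAULT_CLUSTER_CONFIG = ClusterConfig()


@dataclass(frozen=True)
class PlacedGene:
    """A CDRH with coordinates and an RGA class, ready for clustering."""

    gene_id: str
    chrom: str
    start: int
    end: int
    rga_class: RGAClass


def placed_genes_from_assignments(assignments: Iterable) -> list[PlacedGene]:
    """Adapt CDRH assignments (with gene features) for cluster detection.

    Assignments without coordinates are excluded with a warning count.
    """
    placed = []
    missing = 0
    for a in assignments:
        feat = a.rga.feature
        if feat is None:
            missing += 1
            continue
        placed.append(
            PlacedGene(
                gene_id=feat.gene_id,
                chrom=feat.chrom,
                start=feat.start,
                end=feat.end,
                rga_class=a.rga.rga_class,
            )
        )
    if missing:
        logger.warning("%d CDRH(s) without coordinates excluded from clustering", missing)
    return placed


def _cluster_type(members: list[PlacedGene]) -> ClusterType:
    classes = {g.rga_class for g in members}
    if len(classes) > 1:
        return ClusterType.GC_H
    return {
        RGAClass.NLR: ClusterType.GC_NLR,
        RGAClass.RLK: ClusterType.GC_RLK,
        RGAClass.RLP: ClusterType.GC_RLP,
    }.get(next(iter(classes)), ClusterType.GC_H)


def find_clusters(
    genes: Iterable[PlacedGene],
    config: ClusterConfig = DEFAULT_CLUSTER_CONFIG,
    id_prefix: str = "GC",
) -> list[GeneCluster]:
    """Greedy disjoint maximal clustering per chromosome.

    Genes are sorted internally by (chrom, start, end, gene_id), so input
    order never matters. Starting from the leftmost unclustered gene, the
    window extends rightward while the span (max end - min start + 1)
    stays within ``max_span``; windows reaching ``min_members`` are
    emitted and the scan resumes after them.
    """
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    clusters: list[GeneCluster] = []
    serial = 0
    i = 0
    while i < len(ordered):
        anchor = ordered[i]
        members = [anchor]
        max_end = anchor.end
        j = i + 1
        while j < len(ordered) and ordered[j].chrom == anchor.chrom:
            candidate_end = max(max_end, ordered[j].end)
            if candidate_end - anchor.start + 1 > config.max_span:
                break
            members.append(ordered[j])
            max_end = candidate_end
            j += 1
        if len(members) >= config.min_members:
            serial += 1
            ctype = _cluster_type(members)
            if config.notice_members is not None and len(members) > config.notice_members:
                logger.info(
                    "cluster %s_%d on %s has %d members (above the typically "
                    "observed %d)",
                    id_prefix,
                    serial,
                    anchor.chrom,
                    len(members),
                    config.notice_members,
                )
            clusters.append(
                GeneCluster(
                    cluster_id=f"{id_prefix}_{serial:03d}",
                    chrom=anchor.chrom,
                    members=tuple(g.gene_id for g in members),
                    start=anchor.start,
                    end=max_end,
                    cluster_type=ctype,
                )
            )
            i = j
        else:
            i += 1
    return clusters


def summarize_clusters(
    clusters: Iterable[GeneCluster],
    species_code: str = "",
) -> pd.DataFrame:
    """Count clusters by type, with a per-chromosome breakdown.

    Always contains one total row per cluster type (zero-filled), plus one
    row per (chromosome, type) actually observed.
    """
    clusters = list(clusters)
    by_type: Counter = Counter(c.cluster_type.value for c in clusters)
    by_chrom_type: Counter = Counter(
        (c.chrom, c.cluster_type.value) for c in clusters
    )
    rows = [
        {
            "species": species_code,
            "chrom": "*",
            "cluster_type": ct.value,
            "count": by_type.get(ct.value, 0),
        }
        for ct in ClusterType
    ]
    rows.extend(
        {
            "species": species_code,
            "chrom": chrom,
            "cluster_type": ctype,
            "count": n,
        }
        for (chrom, ctype), n in sorted(by_chrom_type.items())
    )
    return pd.DataFrame(rows, columns=["species", "chrom", "cluster_type", "count"])
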