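"""Homology filtering and best-hit assignment of RGAs to cloned R genes.

A cloned disease resistance gene homolog (CDRH) is an RGA whose BLASTp hit
against one of the 49 cloned reference R genes survives three filters —
E-value at most 1e-45, aligned length at least 148 aa, similarity (percent
positives) at least 60% — and which is then assigned to exactly one
reference gene by its best passing hit. All three boundaries are inclusive
on the keep side: the stated removal directions ("greater than",
"less than", "lower than") keep the boundary values themselves.

The one-reference-per-RGA rule makes the per-gene homolog counts a
partition of the CDRH set, which is what lets them sum to a global total.
Disease labels are inherited from the reference gene afterwards, so one
CDRH can feed several disease totals while feeding exactly one gene total.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .formats_io import ReferenceTables
from .model import CDRHAssignment, ClonedRGene, HomologyHit, RGARecord, Subclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Homology-filter thresholds (keep side inclusive).

    max_evalue: BLASTp expectation value ceiling (default 1e-45).
    min_alignment_length: aligned columns floor, in amino acids
        (default 148; an absolute length, not a fraction).
    min_similarity: percent-positives floor (default 60.0%).
    """

    max_evalue: float = 1e-45
    min_alignment_length: int = 148
    min_similarity: float = 60.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0 or self.min_alignment_length <= 0 or self.min_similarity <= 0:
            raise ValueError("all filter thresholds must be > 0")
        if self.min_similarity > 100:
            raise ValueError("min_similarity cannot exceed 100%")

    def passes(self, hit: HomologyHit) -> bool:
        return (
            hit.evalue <= self.max_evalue
            and hit.alignment_length >= self.min_alignment_length
            and hit.similarity >= self.min_similarity
        )


DEFAULT_FILTER = FilterConfig()


def filter_hits(
    hits: Iterable[HomologyHit],
    config: FilterConfig = DEFAULT_FILTER,
) -> list[HomologyHit]:
    """Keep hits passing all three criteria; log per-criterion rejections."""
    kept: list[HomologyHit] = []
    rejected: Counter = Counter()
    for hit in hits:
        ok = True
        if hit.evalue > config.max_evalue:
            rejected["evalue"] += 1
            ok = False
        if hit.alignment_length < config.min_alignment_length:
            rejected["alignment_length"] += 1
            ok = False
        if hit.similarity < config.min_similarity:
            rejected["similarity"] += 1
            ok = False
        if ok:
            kept.append(hit)
    logger.info(
        "homology filter kept %d hits; rejections by criterion: %s",
        len(kept),
        dict(rejected),
    )
    return kept


def hit_preference_key(hit: HomologyHit) -> tuple:
    """Sort key ranking a query's hits from best to worst.

    Minimum E-value first, then maximum bitscore, maximum similarity, and
    lexicographically smallest reference name as the final deterministic
    tie-break.
    """
    return (hit.evalue, -hit.bitscore, -hit.similarity, hit.subject_name)


def assign_best_reference(
    passing_hits: Iterable[HomologyHit],
    rga_table: Mapping[str, RGARecord],
    reference_table: Mapping[str, ClonedRGene],
) -> list[CDRHAssignment]:
    """Assign each RGA with at least one passing hit to one reference gene.

    Hits whose subject is not a known reference raise (all unmatched names
    listed); hits whose query is missing from the RGA table are skipped
    with a warning — this includes proteins that failed RGA classification,
    enforcing that every CDRH is an RGA. Output is sorted by query id.
    """
    hits = list(passing_hits)
    unknown_subjects = sorted(
        {h.subject_name for h in hits if h.subject_name not in reference_table}
    )
    if unknown_subjects:
        raise ValueError(
            f"hits reference unknown cloned gene name(s): {unknown_subjects}"
        )

    best: dict[str, HomologyHit] = {}
    skipped_queries: set = set()
    non_rga = 0
    for hit in hits:
        rga = rga_table.get(hit.query_id)
        if rga is None:
            skipped_queries.add(hit.query_id)
            continue
        if rga.subclass is Subclass.NON_RGA:
            non_rga += 1
            continue
        incumbent = best.get(hit.query_id)
        if incumbent is None or hit_preference_key(hit) < hit_preference_key(incumbent):
            best[hit.query_id] = hit
    if skipped_queries:
        logger.warning(
            "%d hit quer%s not present in the RGA table; skipped",
            len(skipped_queries),
            "y is" if len(skipped_queries) == 1 else "ies are",
        )
    if non_rga:
        logger.info("dropped %d hits from proteins classified NonRGA", non_rga)

    return [
        CDRHAssignment(
            rga=rga_table[query_id],
            reference=reference_table[best[query_id].subject_name],
            best_hit=best[query_id],
        )
        for query_id in sorted(best)
    ]


def map_diseases(
    assignments: Iterable[CDRHAssignment],
    fixture: ReferenceTables,
) -> list[CDRHAssignment]:
    """Attach every disease of the reference gene to each assignment.

    References absent from the disease map get an empty set with a warning;
    they still count toward gene totals.
    """
    out = []
    unmapped: set = set()
    for a in assignments:
        diseases = fixture.gene_disease_map.get(a.reference.name)
        if diseases is None:
            diseases = fixture.gene_disease_map.get(a.reference.alias)
        if diseases is None:
            unmapped.add(a.reference.name)
            diseases = frozenset()
        a.diseases = frozenset(diseases)
        out.append(a)
    if unmapped:
        logger.warning(
            "reference gene(s) absent from the disease map: %s", sorted(unmapped)
        )
    return out
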