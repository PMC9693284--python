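"""Domain retention and diversification of CDRHs versus their references.

Retention is decided on subclass labels: a homolog retains its reference's
RGA domain structure iff the two subclass labels are equal. Diversified
homologs are subcategorized by comparing canonical domain sets — the
minimal architecture each subclass label implies:

    truncation:   domains only removed   (canonical(hom) strictly inside ref)
    addition:     domains only added
    combination:  at least one removed and at least one added

TX and Other-NLR carry an explicit OTHER element in their canonical sets
(TIR/NBS-LRR "with other domains"), so e.g. TN -> TX is a combination (NBS
removed, OTHER added). The "one or two domains" phrasing that usually
accompanies truncation/addition is descriptive, not enforced: removed and
added sets of any size are allowed (RNL -> LRR-RLP removes two and adds
one).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional

import pandas as pd

from .model import (
    CDRHAssignment,
    DomainCategory as D,
    EvolutionCall,
    EvolutionCategory,
    EvolutionStatus,
    Subclass,
)

#: minimal domain architecture implied by each subclass label
CANONICAL_DOMAIN_SETS: dict = {
    Subclass.CN: frozenset({D.CC, D.NBS}),
    Subclass.CNL: frozenset({D.CC, D.NBS, D.LRR}),
    Subclass.NBS: frozenset({D.NBS}),
    Subclass.NL: frozenset({D.NBS, D.LRR}),
    Subclass.TNL: frozenset({D.TIR, D.NBS, D.LRR}),
    Subclass.TN: frozenset({D.TIR, D.NBS}),
    Subclass.TX: frozenset({D.TIR, D.OTHER}),
    Subclass.OTHER_NLR: frozenset({D.NBS, D.LRR, D.OTHER}),
    Subclass.RNL: frozenset({D.RPW8, D.NBS, D.LRR}),
    Subclass.LRR_RLK: frozenset({D.LRR, D.KINASE, D.TM}),
    Subclass.LYSM_RLK: frozenset({D.LYSM, D.KINASE, D.TM}),
    Subclass.OTHER_RLK: frozenset({D.KINASE, D.TM}),
    Subclass.LRR_RLP: frozenset({D.LRR, D.TM}),
    Subclass.LYSM_RLP: frozenset({D.LYSM, D.TM}),
    Subclass.TM: frozenset({D.TM}),
    Subclass.CC: frozenset({D.CC}),
}


def retention_status(
    reference_subclass: Subclass, homolog_subclass: Subclass
) -> EvolutionStatus:
    """RETAINED iff the two subclass labels are equal."""
    if reference_subclass is homolog_subclass:
        return EvolutionStatus.RETAINED
    return EvolutionStatus.DIVERSIFIED


def diversification_category(
    reference_subclass: Subclass, homolog_subclass: Subclass
) -> EvolutionCall:
    """Categorize a subclass pair via canonical domain-set differences.

    Total over subclass pairs with canonical sets; equal labels yield a
    RETAINED call with empty difference sets. Subclasses without a
    canonical set (NonRGA) raise.
    """
    try:
        ref_set = CANONICAL_DOMAIN_SETS[reference_subclass]
        hom_set = CANONICAL_DOMAIN_SETS[homolog_subclass]
    except KeyError as exc:
        raise ValueError(f"no canonical domain set for subclass {exc}") from None
    removed = ref_set - hom_set
    added = hom_set - ref_set
    if not removed and not added:
        return EvolutionCall(
            EvolutionStatus.RETAINED, EvolutionCategory.NONE, frozenset(), frozenset()
        )
    if not added:
        category = EvolutionCategory.TRUNCATION
    elif not removed:
        category = EvolutionCategory.ADDITION
    else:
        category = EvolutionCategory.COMBINATION
    return EvolutionCall(EvolutionStatus.DIVERSIFIED, category, removed, added)


def annotate_evolution(
    assignments: Iterable[CDRHAssignment],
) -> tuple[list, pd.DataFrame]:
    """Attach an EvolutionCall to every assignment; summarize the counts.

    Returns the annotated assignments plus a tidy summary frame with one
    row per (reference subclass, status, category) combination.
    """
    annotated = []
    counts: Counter = Counter()
    for a in assignments:
        call = diversification_category(a.reference.subclass, a.rga.subclass)
        a.evolution = call
        annotated.append(a)
        counts[(a.reference.subclass.value, call.status.value, call.category.value)] += 1
    summary = summarize_evolution_counts(counts)
    return annotated, summary


def evolution_summary_from_pairs(
    pairs: Iterable[tuple[Subclass, Optional[Subclass]]],
) -> pd.DataFrame:
    """Summary frame from bare (reference, homolog) subclass pairs.

    A homolog subclass of None (known diversified, unknown composition)
    is tallied as diversified with category "unknown".
    """
    counts: Counter = Counter()
    for ref, hom in pairs:
        if hom is None:
            counts[(ref.value, EvolutionStatus.DIVERSIFIED.value, "unknown")] += 1
            continue
        call = diversification_category(ref, hom)
        counts[(ref.value, call.status.value, call.category.value)] += 1
    return summarize_evolution_counts(counts)


def summarize_evolution_counts(counts: Counter) -> pd.DataFrame:
    rows = [
        {
            "reference_subclass": ref,
            "status": status,
            "category": category,
            "count": n,
        }
        for (ref, status, category), n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["reference_subclass", "status", "category", "count"]
    )
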