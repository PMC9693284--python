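"""Core value types shared across the CDRH pipeline.

The pipeline classifies proteins into resistance gene analog (RGA)
subclasses from their domain architectures, links RGAs to a curated set of
49 cloned Brassicaceae disease resistance (R) genes by filtered protein
homology, and studies how the homologs' domain architectures were retained
or diversified and how they cluster physically on chromosomes.

Coordinate convention: all genomic coordinates are 1-based inclusive
(GFF3 style) everywhere inside the package; conversion to 0-based
half-open happens only at BED export.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class DomainCategory(enum.Enum):
    """Normalized protein-domain evidence categories.

    Every raw domain label from an annotation tool maps onto exactly one of
    these ten categories; OTHER is the sink for labels with no resistance
    relevance.
    """

    TIR = "TIR"
    CC = "CC"
    RPW8 = "RPW8"
    NBS = "NBS"
    LRR = "LRR"
    LYSM = "LysM"
    KINASE = "KINASE"
    TM = "TM"
    SIGNAL_PEPTIDE = "SIGNAL_PEPTIDE"
    OTHER = "OTHER"


class RGAClass(enum.Enum):
    """The three RGA families plus a sink for non-RGA labels."""

    NLR = "NLR"
    RLK = "RLK"
    RLP = "RLP"
    NONE = "NONE"


class Subclass(enum.Enum):
    """RGA subclass labels, printed the way the literature prints them.

    The first fourteen members are produced by the architecture classifier;
    NON_RGA is its reject label. TM and CC are reference-only labels: two of
    the 49 cloned R genes are a bare transmembrane protein and a bare
    coiled-coil protein, which the classifier never emits but the homology
    layer must represent.
    """

    CN = "CN"
    CNL = "CNL"
    NBS = "NBS"
    NL = "NL"
    TNL = "TNL"
    TN = "TN"
    TX = "TX"
    OTHER_NLR = "Other-NLR"
    RNL = "RNL"
    LRR_RLK = "LRR-RLK"
    LYSM_RLK = "LysM-RLK"
    OTHER_RLK = "Other-RLK"
    LRR_RLP = "LRR-RLP"
    LYSM_RLP = "LysM-RLP"
    NON_RGA = "NonRGA"
    TM = "TM"
    CC = "CC"

    @property
    def rga_class(self) -> RGAClass:
        if self in _NLR_SUBCLASSES:
            return RGAClass.NLR
        if self in _RLK_SUBCLASSES:
            return RGAClass.RLK
        if self in _RLP_SUBCLASSES:
            return RGAClass.RLP
        return RGAClass.NONE

    @classmethod
    def from_label(cls, label: str) -> "Subclass":
        """Parse a printed subclass label (case/punctuation tolerant)."""
        key = label.strip().upper().replace("-", "_").replace(" ", "_")
        try:
            return _LABEL_TO_SUBCLASS[key]
        except KeyError:
            raise ValueError(f"unknown RGA subclass label: {label!r}") from None


_NLR_SUBCLASSES = frozenset(
    {
        Subclass.CN,
        Subclass.CNL,
        Subclass.NBS,
        Subclass.NL,
        Subclass.TNL,
        Subclass.TN,
        Subclass.TX,
        Subclass.OTHER_NLR,
        Subclass.RNL,
    }
)
_RLK_SUBCLASSES = frozenset({Subclass.LRR_RLK, Subclass.LYSM_RLK, Subclass.OTHER_RLK})
_RLP_SUBCLASSES = frozenset({Subclass.LRR_RLP, Subclass.LYSM_RLP})

_LABEL_TO_SUBCLASS = {s.name: s for s in Subclass}
_LABEL_TO_SUBCLASS.update({s.value.upper().replace("-", "_"): s for s in Subclass})
_LABEL_TO_SUBCLASS["NONRGA"] = Subclass.NON_RGA
_LABEL_TO_SUBCLASS["NON_RGA"] = Subclass.NON_RGA


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence: unique id plus amino-acid residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"SequenceRecord {self.id}: empty residues")


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus; start/end are 1-based inclusive base pairs."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) > end ({self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainAnnotation:
    """One normalized domain evidence row for a protein."""

    protein_id: str
    category: DomainCategory
    raw_label: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}:{self.raw_label}: start > end "
                f"({self.start} > {self.end})"
            )


@dataclass
class RGARecord:
    """A protein with an assigned RGA subclass."""

    protein_id: str
    species_code: str
    subclass: Subclass
    domain_set: frozenset = frozenset()
    feature: Optional[GeneFeature] = None

    @property
    def rga_class(self) -> RGAClass:
        return self.subclass.rga_class


@dataclass(frozen=True)
class HomologyHit:
    """One BLASTp tabular row between an RGA query and a cloned-gene subject.

    ``similarity`` carries percent positives when the hit table provides
    them, falling back to percent identity otherwise (flagged by the
    reader); the homology filter operates on this column.
    """

    query_id: str
    subject_name: str
    identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    similarity: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}->{self.subject_name}: negative evalue")
        if not 0 <= self.similarity <= 100:
            raise ValueError(
                f"{self.query_id}->{self.subject_name}: similarity "
                f"{self.similarity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError(
                f"{self.query_id}->{self.subject_name}: alignment length < 1"
            )


@dataclass(frozen=True)
class ClonedRGene:
    """One of the 49 curated cloned R genes used as homology references."""

    name: str
    subclass: Subclass
    diseases: frozenset = frozenset()
    pathogens: frozenset = frozenset()
    accession: str = ""
    alias: str = ""


class EvolutionStatus(enum.Enum):
    RETAINED = "retained"
    DIVERSIFIED = "diversified"


class EvolutionCategory(enum.Enum):
    NONE = "none"
    TRUNCATION = "truncation"
    ADDITION = "addition"
    COMBINATION = "combination"


@dataclass(frozen=True)
class EvolutionCall:
    """Domain retention/diversification of a homolog vs its reference.

    ``removed``/``added`` are differences of canonical domain sets:
    removed = canonical(reference) - canonical(homolog), added the reverse.
    """

    status: EvolutionStatus
    category: EvolutionCategory
    removed: frozenset
    added: frozenset

    def __post_init__(self) -> None:
        retained = self.status is EvolutionStatus.RETAINED
        if retained != (self.category is EvolutionCategory.NONE):
            raise ValueError("status RETAINED iff category NONE")
        expected = _category_for(self.removed, self.added)
        if expected is not self.category:
            raise ValueError(
                f"category {self.category} inconsistent with removed/added sets"
            )


def _category_for(removed: frozenset, added: frozenset) -> EvolutionCategory:
    if not removed and not added:
        return EvolutionCategory.NONE
    if removed and not added:
        return EvolutionCategory.TRUNCATION
    if added and not removed:
        return EvolutionCategory.ADDITION
    return EvolutionCategory.COMBINATION


@dataclass
class CDRHAssignment:
    """An RGA assigned (by best passing hit) to exactly one cloned R gene."""

    rga: RGARecord
    reference: ClonedRGene
    best_hit: HomologyHit
    diseases: frozenset = frozenset()
    evolution: Optional[EvolutionCall] = None


class ClusterType(enum.Enum):
    GC_NLR = "GC_NLR"
    GC_RLK = "GC_RLK"
    GC_RLP = "GC_RLP"
    GC_H = "GC_H"


@dataclass(frozen=True)
class GeneCluster:
    """A maximal run of CDRHs within a bounded chromosomal span.

    Homogeneous clusters (all members one RGA class) are typed GC_NLR,
    GC_RLK or GC_RLP; mixed-class clusters are heterogeneous (GC_H).
    """

    cluster_id: str
    chrom: str
    members: tuple
    start: int
    end: int
    cluster_type: ClusterType

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_members(self) -> int:
        return len(self.members)
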