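"""Domain-architecture classification of proteins into RGA subclasses.

A protein's normalized domain-category set is mapped onto one of 14 RGA
subclasses (or NonRGA) by an explicit first-match decision table:

1. RPW8 + NBS + LRR, with RNL detection enabled -> RNL
2. NBS present: TIR+LRR -> TNL; TIR -> TN; CC+LRR -> CNL; CC -> CN;
   LRR+OTHER -> Other-NLR; LRR -> NL; OTHER -> Other-NLR; bare -> NBS
3. TIR without NBS -> TX
4. kinase + transmembrane: LysM -> LysM-RLK; LRR -> LRR-RLK; else Other-RLK
5. transmembrane without kinase: LRR -> LRR-RLP; LysM -> LysM-RLP; else NonRGA
6. anything else -> NonRGA

RNL detection defaults OFF for predicted proteomes: the upstream subclass
vocabulary this table reconstructs has no RNL output class, so homologs of
RNL reference genes always surface under another label — an asymmetry the
pipeline preserves deliberately (reference cloned genes carry curated
subclass labels instead). TIR outranks CC when both are present (TNL over
CNL), the convention in the NLR literature; transmembrane evidence is
required for every receptor (RLK/RLP) call, so kinase-only proteins are
NonRGA. Signal peptides are parsed but carry no weight in the table.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import DomainAnnotation, DomainCategory, RGARecord, Subclass

logger = logging.getLogger(__name__)

#: predictor tools whose evidence category is fixed by the tool itself
_SOURCE_CATEGORIES = {
    "tmhmm": DomainCategory.TM,
    "phobius_tm": DomainCategory.TM,
    "signalp": DomainCategory.SIGNAL_PEPTIDE,
    "coils": DomainCategory.CC,
}


def _load_label_rules() -> list[tuple[str, DomainCategory]]:
    text = resources.files("cdrh.fixtures").joinpath("domain_labels.tsv").read_text()
    rules = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("pattern\t"):
            continue
        pattern, category = ln.split("\t")
        rules.append((pattern.upper(), DomainCategory(category)))
    return rules


_LABEL_RULES = _load_label_rules()


def normalize_domain_label(raw_label: str, source: str = "") -> DomainCategory:
    """Map a raw domain label (plus its source tool) onto a category.

    Source-tool dispatch first (TM/signal/coiled-coil predictors), then
    ordered case-insensitive substring rules from the packaged lookup;
    unknown labels sink to OTHER. Total: never raises on content.
    """
    if not raw_label:
        raise ValueError("raw_label must be non-empty")
    cat = _SOURCE_CATEGORIES.get(source.strip().lower())
    if cat is not None:
        return cat
    upper = raw_label.upper()
    for pattern, category in _LABEL_RULES:
        if pattern in upper:
            return category
    return DomainCategory.OTHER


@dataclass(frozen=True)
class ClassifierConfig:
    """Knobs of the architecture decision table.

    ``rnl_detection`` turns rule 1 on (OFF by default, see module
    docstring). ``tir_precedence`` keeps TIR above CC when both are
    present; flipping it makes {TIR, CC, NBS, LRR} classify CNL.
    """

    rnl_detection: bool = False
    tir_precedence: bool = True


DEFAULT_CONFIG = ClassifierConfig()


def classify_architecture(
    domain_set: Iterable[DomainCategory],
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> Subclass:
    """Assign the RGA subclass for a set of domain categories (total function)."""
    s = frozenset(domain_set)
    tir = DomainCategory.TIR in s
    cc = DomainCategory.CC in s
    nbs = DomainCategory.NBS in s
    lrr = DomainCategory.LRR in s
    other = DomainCategory.OTHER in s
    kinase = DomainCategory.KINASE in s
    tm = DomainCategory.TM in s
    lysm = DomainCategory.LYSM in s
    rpw8 = DomainCategory.RPW8 in s

    if config.rnl_detection and rpw8 and nbs and lrr:
        return Subclass.RNL
    if nbs:
        n_terminal = [
            (tir, Subclass.TNL, Subclass.TN),
            (cc, Subclass.CNL, Subclass.CN),
        ]
        if not config.tir_precedence:
            n_terminal.reverse()
        for present, with_lrr, without_lrr in n_terminal:
            if present:
                return with_lrr if lrr else without_lrr
        if lrr and other:
            return Subclass.OTHER_NLR
        if lrr:
            return Subclass.NL
        if other:
            return Subclass.OTHER_NLR
        return Subclass.NBS
    if tir:
        return Subclass.TX
    if kinase and tm:
        if lysm:
            return Subclass.LYSM_RLK
        if lrr:
            return Subclass.LRR_RLK
        return Subclass.OTHER_RLK
    if tm:
        if lrr:
            return Subclass.LRR_RLP
        if lysm:
            return Subclass.LYSM_RLP
        return Subclass.NON_RGA
    return Subclass.NON_RGA


def classify_proteome(
    annotations: Iterable[DomainAnnotation],
    species_code: str,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> list[RGARecord]:
    """Classify every annotated protein; keep those that are RGAs.

    Annotation rows for the same protein id are unioned into one domain
    set. Returns one RGARecord per protein with subclass != NonRGA, sorted
    by protein id; per-class counts go to the log.
    """
    domains: dict[str, set] = defaultdict(set)
    for ann in annotations:
        domains[ann.protein_id].add(ann.category)

    records = []
    for protein_id in sorted(domains):
        subclass = classify_architecture(domains[protein_id], config)
        if subclass is Subclass.NON_RGA:
            continue
        records.append(
            RGARecord(
                protein_id=protein_id,
                species_code=species_code,
                subclass=subclass,
                domain_set=frozenset(domains[protein_id]),
            )
        )
    by_class = Counter(r.rga_class.value for r in records)
    logger.info(
        "%s: %d/%d proteins classified as RGAs (%s)",
        species_code,
        len(records),
        len(domains),
        dict(by_class),
    )
    return records


def read_domain_table(path: Union[str, Path]) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV into normalized DomainAnnotations.

    Two layouts are accepted: the InterProScan 11+-column tab layout
    (protein, md5, length, analysis, signature accession, signature
    description, start, stop, ...) detected by column count, or a headered
    5/6-column table (protein_id, source, raw_label, start, end[, score])
    as emitted by the synthetic generator.
    """
    annotations: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            f = line.split("\t")
            if len(f) >= 8 and f[2].isdigit():  # InterProScan layout
                protein_id, source, label = f[0], f[3], f[5]
                if not label or label == "-":
                    label = f[4]
                start, end = int(f[6]), int(f[7])
            elif len(f) >= 5:
                protein_id, source, label = f[0], f[1], f[2]
                start, end = int(f[3]), int(f[4])
            else:
                raise ValueError(f"{path}:{lineno}: unrecognised domain-table row")
            annotations.append(
                DomainAnnotation(
                    protein_id=protein_id,
                    category=normalize_domain_label(label, source),
                    raw_label=label,
                    start=start,
                    end=end,
                    source=source,
                )
            )
    return annotations
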