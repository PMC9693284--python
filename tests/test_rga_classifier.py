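"""Architecture decision table: totality, uniqueness, known calls."""

from itertools import combinations

import pytest

from cdrh.model import DomainAnnotation, DomainCategory as D, RGAClass, Subclass
from cdrh.rga_classifier import (
    ClassifierConfig,
    classify_architecture,
    classify_proteome,
    normalize_domain_label,
)

ALL_CATEGORIES = list(D)


def powerset(categories):
    for r in range(len(categories) + 1):
        yield from (frozenset(c) for c in combinations(categories, r))


# ------------------------------------------------------- label normalization


@pytest.mark.parametrize(
    "raw,source,expected",
    [
        ("NB-ARC", "Pfam", D.NBS),
        ("LRR_8", "Pfam", D.LRR),
        ("Leucine-rich repeat", "SUPERFAMILY", D.LRR),
        ("Pkinase", "Pfam", D.KINASE),
        ("TIR", "Pfam", D.TIR),
        ("RPW8", "Pfam", D.RPW8),
        ("LysM", "Pfam", D.LYSM),
        ("TMhelix", "tmhmm", D.TM),
        ("Coil", "coils", D.CC),
        ("SignalP-noTM", "signalp", D.SIGNAL_PEPTIDE),
        ("Glyco_hydro_18", "Pfam", D.OTHER),
        ("DUF4219", "Pfam", D.OTHER),
    ],
)
def test_normalize_domain_label(raw, source, expected):
    assert normalize_domain_label(raw, source) is expected


def test_normalize_rejects_empty_label():
    with pytest.raises(ValueError):
        normalize_domain_label("")


# ------------------------------------------------------- decision table


@pytest.mark.parametrize(
    "domains,expected",
    [
        ({D.TIR, D.NBS, D.LRR}, Subclass.TNL),
        ({D.TIR, D.NBS}, Subclass.TN),
        ({D.CC, D.NBS, D.LRR}, Subclass.CNL),
        ({D.CC, D.NBS}, Subclass.CN),
        ({D.NBS, D.LRR}, Subclass.NL),
        ({D.NBS}, Subclass.NBS),
        ({D.NBS, D.LRR, D.OTHER}, Subclass.OTHER_NLR),
        ({D.NBS, D.OTHER}, Subclass.OTHER_NLR),
        ({D.TIR}, Subclass.TX),
        ({D.TIR, D.OTHER}, Subclass.TX),
        ({D.KINASE, D.TM, D.LRR}, Subclass.LRR_RLK),
        ({D.KINASE, D.TM, D.LYSM}, Subclass.LYSM_RLK),
        ({D.KINASE, D.TM}, Subclass.OTHER_RLK),
        ({D.TM, D.LRR}, Subclass.LRR_RLP),
        ({D.TM, D.LYSM}, Subclass.LYSM_RLP),
        ({D.TM}, Subclass.NON_RGA),
        ({D.KINASE}, Subclass.NON_RGA),  # receptor calls need TM evidence
        (set(), Subclass.NON_RGA),
        ({D.TIR, D.CC, D.NBS, D.LRR}, Subclass.TNL),  # TIR outranks CC
        ({D.SIGNAL_PEPTIDE, D.OTHER}, Subclass.NON_RGA),
    ],
)
def test_classify_architecture_known_calls(domains, expected):
    assert classify_architecture(domains) is expected


def test_rnl_detection_toggle():
    rnl_arch = {D.RPW8, D.NBS, D.LRR}
    assert classify_architecture(rnl_arch) is Subclass.NL  # default: no RNL class
    on = ClassifierConfig(rnl_detection=True)
    assert classify_architecture(rnl_arch, on) is Subclass.RNL


def test_tir_precedence_flip():
    both = {D.TIR, D.CC, D.NBS, D.LRR}
    assert classify_architecture(both, ClassifierConfig(tir_precedence=False)) is Subclass.CNL


# Independent re-statement of the decision table as an ordered rule list:
# (required categories, forbidden categories, result). Used to check that
# exactly one rule fires for every one of the 1024 domain sets and that the
# classifier agrees with the first firing rule.
def _oracle_rules(rnl_detection):
    N, T, C, L, O, K, M, Y, R = (
        D.NBS, D.TIR, D.CC, D.LRR, D.OTHER, D.KINASE, D.TM, D.LYSM, D.RPW8,
    )
    rules = []
    if rnl_detection:
        rules.append(({R, N, L}, set(), Subclass.RNL))
    rules += [
        ({N, T, L}, set(), Subclass.TNL),
        ({N, T}, {L}, Subclass.TN),
        ({N, C, L}, {T}, Subclass.CNL),
        ({N, C}, {T, L}, Subclass.CN),
        ({N, L, O}, {T, C}, Subclass.OTHER_NLR),
        ({N, L}, {T, C, O}, Subclass.NL),
        ({N, O}, {T, C, L}, Subclass.OTHER_NLR),
        ({N}, {T, C, L, O}, Subclass.NBS),
        ({T}, {N}, Subclass.TX),
        ({K, M, Y}, {N, T}, Subclass.LYSM_RLK),
        ({K, M, L}, {N, T, Y}, Subclass.LRR_RLK),
        ({K, M}, {N, T, Y, L}, Subclass.OTHER_RLK),
        ({M, L}, {N, T, K}, Subclass.LRR_RLP),
        ({M, Y}, {N, T, K, L}, Subclass.LYSM_RLP),
    ]
    return rules


@pytest.mark.parametrize("rnl_detection", [False, True])
def test_exhaustive_enumeration_exactly_one_rule_fires(rnl_detection):
    """Every one of the 2^10 domain sets matches exactly one table row."""
    config = ClassifierConfig(rnl_detection=rnl_detection)
    rules = _oracle_rules(rnl_detection)
    for domain_set in powerset(ALL_CATEGORIES):
        firing = [
            result
            for required, forbidden, result in rules
            if required <= domain_set and not (forbidden & domain_set)
        ]
        if not rnl_detection:
            # without the RNL row the rule list is mutually exclusive
            assert len(firing) <= 1, (domain_set, firing)
        else:
            # the RNL row deliberately shadows NBS rows: first match wins
            assert len(firing) <= 1 or firing[0] is Subclass.RNL, (domain_set, firing)
        expected = firing[0] if firing else Subclass.NON_RGA
        assert classify_architecture(domain_set, config) is expected, domain_set


def test_enumeration_class_partition():
    """Every emitted subclass maps to exactly one of the three RGA families."""
    seen = set()
    for domain_set in powerset(ALL_CATEGORIES):
        sub = classify_architecture(domain_set)
        seen.add(sub)
        if sub is not Subclass.NON_RGA:
            assert sub.rga_class in (RGAClass.NLR, RGAClass.RLK, RGAClass.RLP)
    assert Subclass.TM not in seen and Subclass.CC not in seen  # reference-only
    assert Subclass.RNL not in seen  # needs the explicit toggle


def test_other_removal_only_relaxes_other_nlr_and_tx():
    """Dropping the OTHER category never changes a call except where the
    table conditions on OTHER (Other-NLR and the TX canonical form)."""
    for domain_set in powerset(ALL_CATEGORIES):
        if D.OTHER not in domain_set:
            continue
        with_other = classify_architecture(domain_set)
        without = classify_architecture(domain_set - {D.OTHER})
        if with_other is not without:
            assert with_other in (Subclass.OTHER_NLR, Subclass.TX, Subclass.NON_RGA)


# ------------------------------------------------------- proteome level


def _ann(pid, cats):
    return [
        DomainAnnotation(pid, c, raw_label=c.value, start=1, end=10) for c in cats
    ]


def test_classify_proteome_keeps_only_rgas():
    annotations = (
        _ann("p1", [D.TIR, D.NBS, D.LRR])
        + _ann("p2", [D.KINASE, D.TM])
        + _ann("p3", [D.OTHER])
    )
    records = classify_proteome(annotations, "Aal")
    assert [(r.protein_id, r.subclass) for r in records] == [
        ("p1", Subclass.TNL),
        ("p2", Subclass.OTHER_RLK),
    ]
    assert all(r.species_code == "Aal" for r in records)


def test_classify_proteome_unions_rows_per_protein():
    annotations = _ann("p1", [D.NBS]) + _ann("p1", [D.LRR, D.TIR])
    (rec,) = classify_proteome(annotations, "Csa")
    assert rec.subclass is Subclass.TNL
    assert rec.domain_set == frozenset({D.NBS, D.LRR, D.TIR})
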