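"""Homology filter boundaries, best-reference assignment, disease mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdrh.cdrh_identifier import (
    FilterConfig,
    assign_best_reference,
    filter_hits,
    hit_preference_key,
    map_diseases,
)
from cdrh.model import ClonedRGene, HomologyHit, RGARecord, Subclass


def hit(query="q1", subject="At_BAK1", evalue=1e-60, sim=70.0, aln=200, bits=400.0):
    return HomologyHit(
        query_id=query,
        subject_name=subject,
        identity=sim - 5.0,
        alignment_length=aln,
        evalue=evalue,
        bitscore=bits,
        similarity=sim,
    )


# ---------------------------------------------------------------- filter


@pytest.mark.parametrize(
    "evalue,aln,sim,kept",
    [
        (1e-50, 200, 70.0, True),  # comfortably passing
        (1e-45, 148, 60.0, True),  # all three exactly on the boundary
        (2e-45, 200, 70.0, False),  # worse than E-45 is removed
        (1e-44, 200, 70.0, False),
        (1e-50, 147, 70.0, False),  # below 148 aligned aa is removed
        (1e-50, 148, 70.0, True),
        (1e-50, 200, 59.99, False),  # below 60% similarity is removed
        (0.0, 148, 60.0, True),  # exact zero passes any ceiling
    ],
)
def test_filter_boundaries(evalue, aln, sim, kept):
    result = filter_hits([hit(evalue=evalue, aln=aln, sim=sim)])
    assert (len(result) == 1) is kept


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(max_evalue=0)
    with pytest.raises(ValueError):
        FilterConfig(min_similarity=101)


hit_strategy = st.builds(
    hit,
    query=st.sampled_from(["q1", "q2", "q3"]),
    evalue=st.floats(min_value=0, max_value=1e-30, allow_nan=False),
    sim=st.floats(min_value=0, max_value=100, allow_nan=False),
    aln=st.integers(min_value=1, max_value=600),
)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    hits=st.lists(hit_strategy, max_size=30),
    tighter_evalue=st.floats(min_value=1e-60, max_value=1e-45),
    tighter_aln=st.integers(min_value=148, max_value=300),
    tighter_sim=st.floats(min_value=60.0, max_value=90.0),
)
def test_tightening_any_threshold_never_grows_kept_set(
    hits, tighter_evalue, tighter_aln, tighter_sim
):
    base = set(map(id, filter_hits(hits)))
    tight = FilterConfig(
        max_evalue=tighter_evalue,
        min_alignment_length=tighter_aln,
        min_similarity=tighter_sim,
    )
    assert set(map(id, filter_hits(hits, tight))) <= base


# ---------------------------------------------------------------- assignment

RGAS = {
    "q1": RGARecord("q1", "Aal", Subclass.TNL),
    "q2": RGARecord("q2", "Aal", Subclass.LRR_RLK),
}
REFS = {
    name: ClonedRGene(name, Subclass.TNL)
    for name in ("At_WRR4a", "At_WRR4b", "At_RPP4", "At_RPP5")
}


def test_assignment_takes_minimum_evalue():
    hits = [
        hit(query="q1", subject="At_WRR4a", evalue=1e-80),
        hit(query="q1", subject="At_WRR4b", evalue=1e-60),
    ]
    (a,) = assign_best_reference(hits, RGAS, REFS)
    assert a.reference.name == "At_WRR4a"


def test_assignment_full_tie_breaks_lexicographically():
    hits = [
        hit(query="q1", subject="At_RPP5", evalue=1e-70, bits=500.0, sim=80.0),
        hit(query="q1", subject="At_RPP4", evalue=1e-70, bits=500.0, sim=80.0),
    ]
    (a,) = assign_best_reference(hits, RGAS, REFS)
    assert a.reference.name == "At_RPP4"


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    pair=st.tuples(
        st.builds(
            hit,
            subject=st.sampled_from(sorted(REFS)),
            evalue=st.sampled_from([1e-80, 1e-70, 1e-60]),
            bits=st.sampled_from([300.0, 400.0]),
            sim=st.sampled_from([65.0, 75.0]),
        ),
        st.builds(
            hit,
            subject=st.sampled_from(sorted(REFS)),
            evalue=st.sampled_from([1e-80, 1e-70, 1e-60]),
            bits=st.sampled_from([300.0, 400.0]),
            sim=st.sampled_from([65.0, 75.0]),
        ),
    )
)
def test_preference_key_agrees_with_rule_statement(pair):
    """The comparator prefers min evalue, then max bitscore, then max
    similarity, then the lexicographically smaller reference name."""
    a, b = pair
    if a.evalue != b.evalue:
        expected_a_wins = a.evalue < b.evalue
    elif a.bitscore != b.bitscore:
        expected_a_wins = a.bitscore > b.bitscore
    elif a.similarity != b.similarity:
        expected_a_wins = a.similarity > b.similarity
    else:
        expected_a_wins = a.subject_name <= b.subject_name
    assert (hit_preference_key(a) <= hit_preference_key(b)) is expected_a_wins


def test_assignment_partitions_queries():
    hits = [
        hit(query="q1", subject="At_WRR4a"),
        hit(query="q1", subject="At_RPP4", evalue=1e-90),
        hit(query="q2", subject="At_RPP5"),
    ]
    assignments = assign_best_reference(hits, RGAS, REFS)
    assert len(assignments) == len({a.rga.protein_id for a in assignments}) == 2


def test_assignment_rejects_unknown_reference_and_skips_unknown_query(caplog):
    with pytest.raises(ValueError, match="At_NOPE"):
        assign_best_reference([hit(subject="At_NOPE")], RGAS, REFS)
    with caplog.at_level("WARNING"):
        assert assign_best_reference([hit(query="ghost", subject="At_RPP4")], RGAS, REFS) == []
    assert "not present in the RGA table" in caplog.text


def test_assignment_drops_non_rga_queries(caplog):
    table = dict(RGAS)
    table["q9"] = RGARecord("q9", "Aal", Subclass.NON_RGA)
    with caplog.at_level("INFO"):
        assert assign_best_reference([hit(query="q9", subject="At_RPP4")], table, REFS) == []


def test_empty_hit_list_yields_no_assignments():
    assert assign_best_reference([], RGAS, REFS) == []


# ---------------------------------------------------------------- diseases


def test_map_diseases_inherits_reference_set(curated_tables):
    rlm3 = curated_tables.cloned_genes["At_RLM3"]
    wrr1 = curated_tables.cloned_genes["Bju_WRR1"]
    assignments = [
        type("A", (), {"reference": rlm3, "diseases": frozenset()})(),
        type("A", (), {"reference": wrr1, "diseases": frozenset()})(),
    ]
    out = map_diseases(assignments, curated_tables)
    assert out[0].diseases == {"blackleg", "grey mould", "Alternaria black spot"}
    assert out[1].diseases == {"white rust"}


def test_map_diseases_missing_gene_warns(curated_tables, caplog):
    orphan = ClonedRGene("Zz_FAKE", Subclass.TNL)
    a = type("A", (), {"reference": orphan, "diseases": None})()
    with caplog.at_level("WARNING"):
        (out,) = map_diseases([a], curated_tables)
    assert out.diseases == frozenset()
    assert "absent from the disease map" in caplog.text
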