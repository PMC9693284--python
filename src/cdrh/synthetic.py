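"""Seeded synthetic proteomes with planted homologs and gene clusters.

The generator emulates the statistical structure the pipeline assumes:
proteomes whose domain architectures follow the surveyed RGA subclass
composition, planted homologs of the packaged cloned R genes whose hit
statistics sit strictly on the keep side of all three homology filters
while decoy hits each fail at least one filter (the failing criterion
chosen uniformly so every filter is independently exercised), subclass
retention with a controlled probability, and gene clusters placed within a
bounded span and separated by gaps wide enough that cluster detection is
unambiguous. Homologs of RNL references are always planted diversified:
the architecture classifier has no RNL output class, so retention is
impossible for them by construction — mirroring the survey this package
models.

Everything is driven by one named RNG seeded once; the same configuration
yields byte-identical output files. The generator emits hit tables in
BLAST tabular form rather than running an aligner: the pipeline's
computation starts after the alignment step.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml
from scipy.stats import binomtest

from .cluster_detector import PlacedGene
from .domain_evolution import CANONICAL_DOMAIN_SETS
from .formats_io import ReferenceTables, load_reference_tables, strip_transcript_suffix
from .model import (
    CDRHAssignment,
    DomainCategory as D,
    GeneCluster,
    RGAClass,
    Subclass,
)
from .rga_classifier import DEFAULT_CONFIG, classify_architecture

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: per-category sequence motif, annotation source and raw label
_DOMAIN_TOKENS = {
    D.TIR: ("WDAFISYAGEDR", "Pfam", "TIR"),
    D.CC: ("LEQELKELKELQ", "coils", "Coil"),
    D.RPW8: ("WERPWEVLPDLV", "Pfam", "RPW8"),
    D.NBS: ("GMGGLGKTTLAR", "Pfam", "NB-ARC"),
    D.LRR: ("LDLSGNKLSGEIP", "Pfam", "LRR_8"),
    D.LYSM: ("YVVKSGDTLSSIA", "Pfam", "LysM"),
    D.KINASE: ("GEGGFGKVYKGV", "Pfam", "Pkinase"),
    D.TM: ("LLIIVVLLAVFV", "tmhmm", "TMhelix"),
    D.SIGNAL_PEPTIDE: ("MKLLFLVLALLA", "signalp", "SignalP-noTM"),
    D.OTHER: ("WGGQRSDTNHKA", "Pfam", "Glyco_hydro_18"),
}

#: deterministic domain order within a synthetic protein (N- to C-terminal)
_DOMAIN_ORDER = (
    D.SIGNAL_PEPTIDE,
    D.TIR,
    D.CC,
    D.RPW8,
    D.LYSM,
    D.LRR,
    D.NBS,
    D.OTHER,
    D.TM,
    D.KINASE,
)

#: subclasses the architecture classifier can emit and reproduce from their
#: canonical sets under the default configuration (RNL detection off)
PLANTABLE_SUBCLASSES = tuple(
    s
    for s in Subclass
    if s not in (Subclass.NON_RGA, Subclass.TM, Subclass.CC, Subclass.RNL)
    and classify_architecture(CANONICAL_DOMAIN_SETS[s], DEFAULT_CONFIG) is s
)

#: default proteome subclass composition: the surveyed 3738-RGA breakdown
#: (195 TNL, 161 NL, 161 TX, 110 CNL, 53 TN, 51 NBS, 26 CN, 34 Other-NLR,
#: 1486 Other-RLK, 982 LRR-RLK, 14 LysM-RLK, 457 LRR-RLP, 8 LysM-RLP)
#: padded with a NonRGA share so the classifier's reject path is exercised
_DEFAULT_MIX = {
    Subclass.TNL: 195,
    Subclass.NL: 161,
    Subclass.TX: 161,
    Subclass.CNL: 110,
    Subclass.TN: 53,
    Subclass.NBS: 51,
    Subclass.CN: 26,
    Subclass.OTHER_NLR: 34,
    Subclass.OTHER_RLK: 1486,
    Subclass.LRR_RLK: 982,
    Subclass.LYSM_RLK: 14,
    Subclass.LRR_RLP: 457,
    Subclass.LYSM_RLP: 8,
    Subclass.NON_RGA: 935,
}


@dataclass(frozen=True)
class HitParams:
    """Uniform sampling ranges for one class of BLASTp hit statistics."""

    log10_evalue: tuple = (-180.0, -46.0)
    similarity: tuple = (65.0, 95.0)
    alignment_length: tuple = (160, 400)


#: decoy ranges: each range is the FAIL side of its filter criterion
DECOY_FAIL_PARAMS = HitParams(
    log10_evalue=(-44.0, -5.0),
    similarity=(20.0, 59.0),
    alignment_length=(30, 147),
)


@dataclass
class SimConfig:
    """Synthetic-study configuration; defaults mirror the survey conditions.

    seed drives a single named RNG; genes_per_species times n_species sets
    the proteome scale; homolog_fraction is the probability a gene is a
    true homolog of some reference (drawn with probability proportional to
    the reference's surveyed homolog total); retention_prob is the
    probability a plantable homolog keeps its reference's subclass (the
    surveyed headline retention); diversification_mix weights truncation /
    addition / combination for the rest. Cluster geometry: planted
    clusters stay within cluster_span_max and every placed entity is
    separated by more than intercluster_gap_min, so detection has a unique
    correct answer.
    """

    seed: int = 1
    n_species: int = 3
    genes_per_species: int = 1250
    subclass_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    n_references: int = 49
    homolog_fraction: float = 0.85
    retention_prob: float = 0.63
    diversification_mix: dict = field(
        default_factory=lambda: {"truncation": 0.25, "addition": 0.25, "combination": 0.5}
    )
    true_hit_params: HitParams = field(default_factory=HitParams)
    decoy_hit_params: HitParams = field(default_factory=lambda: DECOY_FAIL_PARAMS)
    n_clusters: int = 6
    cluster_size_range: tuple = (2, 8)
    cluster_span_max: int = 200_000
    intercluster_gap_min: int = 250_000
    n_chromosomes: int = 8
    chromosome_length: int = 60_000_000

    def __post_init__(self) -> None:
        if not 0 <= self.homolog_fraction <= 1 or not 0 <= self.retention_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.diversification_mix.values()) - 1.0) > 1e-9:
            raise ValueError("diversification_mix must sum to 1")
        if self.intercluster_gap_min <= self.cluster_span_max:
            raise ValueError("intercluster_gap_min must exceed cluster_span_max")
        if not 1 <= self.n_references <= 49:
            raise ValueError("n_references must be in 1..49")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subclass_mix" in raw:
            raw["subclass_mix"] = {
                Subclass.from_label(k): v for k, v in raw["subclass_mix"].items()
            }
        for key in ("true_hit_params", "decoy_hit_params"):
            if key in raw:
                raw[key] = HitParams(**{k: tuple(v) for k, v in raw[key].items()})
        for key in ("cluster_size_range",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimResult:
    """Paths of the emitted files plus the in-memory truth table."""

    out_dir: Path
    truth: dict
    paths: dict


# ---------------------------------------------------------------------------
# diversification candidates
# ---------------------------------------------------------------------------


def _diversification_candidates(reference_subclass: Subclass) -> dict:
    """Plantable homolog subclasses per category for one reference subclass."""
    ref_set = CANONICAL_DOMAIN_SETS[reference_subclass]
    out = {"truncation": [], "addition": [], "combination": []}
    for sub in PLANTABLE_SUBCLASSES:
        if sub is reference_subclass:
            continue
        hom_set = CANONICAL_DOMAIN_SETS[sub]
        removed, added = ref_set - hom_set, hom_set - ref_set
        if removed and not added:
            out["truncation"].append(sub)
        elif added and not removed:
            out["addition"].append(sub)
        elif removed and added:
            out["combination"].append(sub)
    return out


def _draw_diversified_subclass(
    rng: np.random.Generator, reference_subclass: Subclass, mix: dict
) -> tuple[Subclass, str]:
    candidates = _diversification_candidates(reference_subclass)
    feasible = {c: w for c, w in mix.items() if candidates.get(c)}
    if not feasible:
        raise ValueError(
            f"no diversification candidate exists for reference subclass "
            f"{reference_subclass.value}"
        )
    cats = sorted(feasible)
    weights = np.array([feasible[c] for c in cats])
    category = cats[rng.choice(len(cats), p=weights / weights.sum())]
    pool = candidates[category]
    return pool[rng.integers(len(pool))], category


# ---------------------------------------------------------------------------
# per-gene synthesis
# ---------------------------------------------------------------------------


_NON_RGA_ARCHITECTURES = (
    frozenset(),
    frozenset({D.OTHER}),
    frozenset({D.KINASE}),
    frozenset({D.TM}),
    frozenset({D.CC}),
    frozenset({D.SIGNAL_PEPTIDE, D.OTHER}),
)


def _architecture_for(rng: np.random.Generator, subclass: Subclass) -> frozenset:
    """A domain set that classifies exactly to ``subclass`` (validated)."""
    if subclass is Subclass.NON_RGA:
        arch = _NON_RGA_ARCHITECTURES[rng.integers(len(_NON_RGA_ARCHITECTURES))]
    else:
        arch = set(CANONICAL_DOMAIN_SETS[subclass])
        for extra in (D.SIGNAL_PEPTIDE, D.OTHER):
            if extra not in arch and rng.random() < 0.25:
                if classify_architecture(arch | {extra}, DEFAULT_CONFIG) is subclass:
                    arch.add(extra)
        arch = frozenset(arch)
    got = classify_architecture(arch, DEFAULT_CONFIG)
    if got is not subclass:
        raise AssertionError(
            f"planted architecture {sorted(d.value for d in arch)} classifies "
            f"to {got.value}, wanted {subclass.value}"
        )
    return arch


def _build_sequence(
    rng: np.random.Generator, architecture: frozenset
) -> tuple[str, list]:
    """Synthetic residues with literal per-domain motif tokens.

    Returns the sequence and (category, start, end) motif positions,
    1-based inclusive in amino acids.
    """
    parts = ["M"]
    pos = 1
    placements = []
    for cat in _DOMAIN_ORDER:
        if cat not in architecture:
            continue
        filler = "".join(rng.choice(AMINO_ACIDS, size=int(rng.integers(5, 21))))
        parts.append(filler)
        pos += len(filler)
        motif = _DOMAIN_TOKENS[cat][0]
        placements.append((cat, pos + 1, pos + len(motif)))
        parts.append(motif)
        pos += len(motif)
    tail = "".join(rng.choice(AMINO_ACIDS, size=int(rng.integers(10, 31))))
    parts.append(tail)
    return "".join(parts), placements


def _draw_hit(
    rng: np.random.Generator,
    params: HitParams,
    fail_criterion: Optional[str] = None,
    fail_params: Optional[HitParams] = None,
) -> tuple[float, float, int]:
    """(evalue, similarity, alignment length); one criterion optionally
    drawn from its fail range instead."""
    src = {
        "evalue": params.log10_evalue,
        "similarity": params.similarity,
        "alignment_length": params.alignment_length,
    }
    if fail_criterion is not None:
        assert fail_params is not None
        src[fail_criterion] = {
            "evalue": fail_params.log10_evalue,
            "similarity": fail_params.similarity,
            "alignment_length": fail_params.alignment_length,
        }[fail_criterion]
    evalue = float(10.0 ** rng.uniform(*src["evalue"]))
    similarity = float(rng.uniform(*src["similarity"]))
    aln = int(rng.integers(src["alignment_length"][0], src["alignment_length"][1] + 1))
    return evalue, similarity, aln


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _place_entities(
    rng: np.random.Generator,
    entities: list,
    config: SimConfig,
    species_code: str,
) -> dict:
    """Assign coordinates to clusters and singleton genes.

    ``entities`` is a list of lists of gene ids (clusters first, then
    singletons); every entity ends more than intercluster_gap_min away
    from the next. Returns gene_id -> (chrom, start, end). Raises when the
    chromosomes cannot hold everything, reporting the required minimum
    length.
    """
    cursors = {
        f"{species_code}_chr{i + 1}": int(rng.integers(10_000, 50_000))
        for i in range(config.n_chromosomes)
    }
    coords: dict = {}
    lo, hi = config.cluster_size_range
    max_gene_len = 4000
    budget_gap_hi = max(
        2000, (config.cluster_span_max - hi * max_gene_len) // max(hi - 1, 1)
    )
    for genes in entities:
        # worst-case extent of this entity
        worst = len(genes) * max_gene_len + max(len(genes) - 1, 0) * budget_gap_hi
        chrom = min(cursors, key=lambda c: (cursors[c], c))
        if cursors[chrom] + worst > config.chromosome_length:
            shortest_needed = cursors[chrom] + worst
            raise ValueError(
                f"chromosomes too short to place all genes: need at least "
                f"{shortest_needed} bp per chromosome (configured "
                f"{config.chromosome_length})"
            )
        pos = cursors[chrom]
        start_of_entity = pos
        max_end = pos
        for k, gene_id in enumerate(genes):
            if k > 0:
                pos += int(rng.integers(1000, budget_gap_hi + 1))
            length = int(rng.integers(1000, max_gene_len + 1))
            end = pos + length - 1
            coords[gene_id] = (chrom, pos, end)
            max_end = max(max_end, end)
            pos = end + 1
        span = max_end - start_of_entity + 1
        if len(genes) > 1 and span > config.cluster_span_max:
            raise AssertionError(f"planted cluster span {span} exceeds limit")
        cursors[chrom] = max_end + config.intercluster_gap_min + int(
            rng.integers(10_000, 100_000)
        )
    return coords


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate(
    config: SimConfig,
    out_dir,
    fixture: Optional[ReferenceTables] = None,
) -> SimResult:
    """Generate domains.tsv, hits.tsv, genes.gff3, proteins.fasta, truth.json.

    Identical configurations (including seed) produce byte-identical
    files. A self-validation pass asserts that every planted architecture
    classifies to its planted subclass, every true hit passes all three
    homology filters, and every decoy hit fails at least one.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if fixture is None:
        fixture = load_reference_tables()

    ref_rows = fixture.homolog_counts[: config.n_references]
    references = [fixture.cloned_genes[r.gene] for r in ref_rows]
    weights = np.array(
        [
            r.total if fixture.cloned_genes[r.gene].subclass in
            set(PLANTABLE_SUBCLASSES) | {Subclass.RNL} else 0
            for r in ref_rows
        ],
        dtype=float,
    )
    if weights.sum() == 0:
        weights = np.array(
            [
                1.0 if ref.subclass in set(PLANTABLE_SUBCLASSES) | {Subclass.RNL} else 0.0
                for ref in references
            ]
        )
    ref_probs = weights / weights.sum()

    mix_subclasses = sorted(config.subclass_mix, key=lambda s: s.name)
    mix_weights = np.array([config.subclass_mix[s] for s in mix_subclasses], dtype=float)
    mix_probs = mix_weights / mix_weights.sum()

    species_codes = sorted(fixture.species_codes.values())[: config.n_species]
    # prefer the three chromosome-assigned study genomes when available
    preferred = [c for c in ("Aal", "Csa", "Chi") if c in fixture.species_codes.values()]
    if len(preferred) >= config.n_species:
        species_codes = preferred[: config.n_species]

    genes: dict = {}  # gene_id -> truth record
    sequences: list = []
    domain_rows: list = []
    hit_rows: list = []

    for code in species_codes:
        for g in range(config.genes_per_species):
            gene_id = f"{code}_g{g + 1:05d}"
            protein_id = f"{gene_id}.1"
            is_homolog = bool(rng.random() < config.homolog_fraction)
            reference = None
            category = None
            if is_homolog:
                reference = references[rng.choice(len(references), p=ref_probs)]
                if reference.subclass is Subclass.RNL:
                    # retention impossible: the classifier has no RNL output
                    subclass, category = _draw_diversified_subclass(
                        rng, reference.subclass, config.diversification_mix
                    )
                elif rng.random() < config.retention_prob:
                    subclass, category = reference.subclass, "retention"
                else:
                    subclass, category = _draw_diversified_subclass(
                        rng, reference.subclass, config.diversification_mix
                    )
            else:
                subclass = mix_subclasses[rng.choice(len(mix_subclasses), p=mix_probs)]

            architecture = _architecture_for(rng, subclass)
            residues, placements = _build_sequence(rng, architecture)
            sequences.append((protein_id, residues))
            for cat, start, end in placements:
                _, source, label = _DOMAIN_TOKENS[cat]
                domain_rows.append((protein_id, source, label, start, end))

            if is_homolog:
                evalue, similarity, aln = _draw_hit(rng, config.true_hit_params)
                assert (
                    evalue <= 1e-45 and aln >= 148 and similarity >= 60.0
                ), "true hit must pass all three homology filters"
            elif subclass is not Subclass.NON_RGA or rng.random() < 0.5:
                reference_decoy = references[rng.choice(len(references), p=ref_probs)]
                fail = ("evalue", "similarity", "alignment_length")[rng.integers(3)]
                evalue, similarity, aln = _draw_hit(
                    rng,
                    config.true_hit_params,
                    fail_criterion=fail,
                    fail_params=config.decoy_hit_params,
                )
                assert not (
                    evalue <= 1e-45 and aln >= 148 and similarity >= 60.0
                ), "decoy hit must fail at least one homology filter"
                hit_rows.append(
                    _hit_row(rng, protein_id, reference_decoy.name, evalue, similarity,
                             aln, len(residues))
                )
                genes[gene_id] = _gene_truth(
                    code, subclass, architecture, False, None, None
                )
                continue
            else:
                genes[gene_id] = _gene_truth(
                    code, subclass, architecture, False, None, None
                )
                continue

            hit_rows.append(
                _hit_row(rng, protein_id, reference.name, evalue, similarity, aln,
                         len(residues))
            )
            genes[gene_id] = _gene_truth(
                code, subclass, architecture, True, reference.name, category
            )

    # ---- clusters ----------------------------------------------------
    truth_clusters: list = []
    coords: dict = {}
    class_of = {
        gid: Subclass.from_label(rec["subclass"]).rga_class
        for gid, rec in genes.items()
    }
    for code in species_codes:
        pool = {
            gid
            for gid, rec in genes.items()
            if rec["species"] == code and rec["is_homolog"]
        }
        entities: list = []
        for k in range(config.n_clusters):
            size = int(
                rng.integers(config.cluster_size_range[0], config.cluster_size_range[1] + 1)
            )
            heterogeneous = bool(rng.random() < 10 / 72)
            members = _pick_cluster_members(rng, pool, class_of, size, heterogeneous)
            pool -= set(members)
            entities.append(members)
        n_planted_clusters = len(entities)
        # everything else is isolated
        remaining = sorted(
            gid for gid, rec in genes.items() if rec["species"] == code
            and gid not in coords and all(gid not in e for e in entities)
        )
        entities.extend([gid] for gid in remaining)
        placed = _place_entities(rng, entities, config, code)
        coords.update(placed)
        for members in entities[:n_planted_clusters]:
            classes = {class_of[g].value for g in members}
            ctype = f"GC_{next(iter(classes))}" if len(classes) == 1 else "GC_H"
            truth_clusters.append(
                {
                    "species": code,
                    "chrom": placed[members[0]][0],
                    "members": sorted(members),
                    "cluster_type": ctype,
                }
            )

    truth = {
        "config": _config_dict(config),
        "genes": genes,
        "clusters": sorted(truth_clusters, key=lambda c: (c["chrom"], c["members"])),
    }
    for gid, (chrom, start, end) in coords.items():
        genes[gid]["chrom"] = chrom
        genes[gid]["start"] = start
        genes[gid]["end"] = end

    paths = _write_outputs(out_dir, sequences, domain_rows, hit_rows, coords, truth)
    return SimResult(out_dir=out_dir, truth=truth, paths=paths)


def _gene_truth(species, subclass, architecture, is_homolog, reference, category):
    return {
        "species": species,
        "subclass": subclass.value,
        "domains": sorted(d.value for d in architecture),
        "is_homolog": is_homolog,
        "reference": reference,
        "category": category,
    }


def _hit_row(rng, protein_id, subject, evalue, similarity, aln, qlen):
    identity = max(similarity - float(rng.uniform(3.0, 12.0)), 10.0)
    bitscore = round(max(50.0, 30.0 - 2.0 * np.log10(max(evalue, 1e-300))), 1)
    mismatch = int(round(aln * (100.0 - identity) / 100.0))
    return (
        protein_id,
        subject,
        f"{identity:.1f}",
        str(aln),
        str(mismatch),
        "0",
        "1",
        str(aln),
        "1",
        str(aln),
        f"{evalue:.3e}",
        f"{bitscore:.1f}",
        f"{similarity:.1f}",
        str(qlen),
    )


def _pick_cluster_members(rng, pool, class_of, size, heterogeneous) -> list:
    ordered = sorted(pool)
    if not heterogeneous:
        by_class: dict = {}
        for gid in ordered:
            by_class.setdefault(class_of[gid], []).append(gid)
        viable = [
            (cls, members) for cls, members in sorted(by_class.items(), key=lambda kv: kv[0].value)
            if len(members) >= size
        ]
        if not viable:
            raise ValueError("not enough homolog genes of one class to plant a cluster")
        cls_weights = np.array(
            [{"NLR": 38.0, "RLK": 17.0, "RLP": 7.0}.get(cls.value, 1.0) for cls, _ in viable]
        )
        cls, members = viable[rng.choice(len(viable), p=cls_weights / cls_weights.sum())]
        idx = rng.choice(len(members), size=size, replace=False)
        return [members[i] for i in sorted(idx)]
    classes = sorted({class_of[g] for g in ordered}, key=lambda c: c.value)
    if len(classes) < 2 or len(ordered) < size:
        raise ValueError("not enough homolog genes to plant a heterogeneous cluster")
    # guarantee two classes, then fill freely
    first = [g for g in ordered if class_of[g] is classes[0]]
    second = [g for g in ordered if class_of[g] is classes[1]]
    members = [
        first[rng.integers(len(first))],
        second[rng.integers(len(second))],
    ]
    rest = [g for g in ordered if g not in members]
    extra = size - 2
    if extra > 0:
        idx = rng.choice(len(rest), size=extra, replace=False)
        members.extend(rest[i] for i in idx)
    return sorted(members)


def _config_dict(config: SimConfig) -> dict:
    raw = asdict(config)
    raw["subclass_mix"] = {s.value: v for s, v in config.subclass_mix.items()}
    return json.loads(json.dumps(raw, default=list))


def _write_outputs(out_dir, sequences, domain_rows, hit_rows, coords, truth) -> dict:
    paths = {
        "fasta": out_dir / "proteins.fasta",
        "domains": out_dir / "domains.tsv",
        "hits": out_dir / "hits.tsv",
        "gff3": out_dir / "genes.gff3",
        "truth": out_dir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for protein_id, residues in sequences:
            fh.write(f">{protein_id}\n")
            for i in range(0, len(residues), 60):
                fh.write(residues[i : i + 60] + "\n")
    with open(paths["domains"], "w") as fh:
        fh.write("protein_id\tsource\traw_label\tstart\tend\n")
        for row in domain_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(paths["hits"], "w") as fh:
        for row in hit_rows:
            fh.write("\t".join(row) + "\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, (chrom, start, end) in sorted(
            coords.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0])
        ):
            fh.write(
                f"{chrom}\tcdrh-sim\tgene\t{start}\t{end}\t.\t+\t.\tID={gene_id}\n"
            )
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Pipeline-vs-truth metrics for one synthetic run."""

    assignment_precision: float
    assignment_recall: float
    n_assigned: int
    n_true_homologs: int
    retention_estimate: float
    retention_ci: tuple
    retention_n: int
    cluster_precision: float
    cluster_recall: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["retention_ci"] = list(self.retention_ci)
        return d


def estimate_recovery(
    assignments: Iterable[CDRHAssignment],
    clusters: Iterable[GeneCluster],
    truth: dict,
) -> RecoveryReport:
    """Compare pipeline output against the generator's truth table.

    Assignment precision/recall compare (gene, reference) pairs; the
    retention estimate is the retained fraction among homologs of
    references where retention is possible (RNL references are excluded —
    their homologs can never be called retained), with an exact binomial
    95% confidence interval; cluster precision/recall require exact
    member-set matches.
    """
    predicted = {}
    for a in assignments:
        gene_id = strip_transcript_suffix(a.rga.protein_id)
        predicted[gene_id] = a
    truth_pairs = {
        gid: rec["reference"]
        for gid, rec in truth["genes"].items()
        if rec["is_homolog"]
    }
    missing = set(predicted) - set(truth["genes"])
    if missing:
        raise ValueError(f"assignments for unknown gene ids: {sorted(missing)[:5]}")
    pred_pairs = {(gid, a.reference.name) for gid, a in predicted.items()}
    true_pairs = set(truth_pairs.items())
    tp = len(pred_pairs & true_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0

    k = n = 0
    for gid, a in predicted.items():
        rec = truth["genes"].get(gid)
        if rec is None or not rec["is_homolog"]:
            continue
        if a.reference.subclass is Subclass.RNL:
            continue
        n += 1
        if a.rga.subclass is a.reference.subclass:
            k += 1
    if n:
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        estimate, interval = k / n, (float(ci.low), float(ci.high))
    else:
        estimate, interval = float("nan"), (0.0, 1.0)

    pred_sets = {frozenset(c.members) for c in clusters}
    true_sets = {frozenset(c["members"]) for c in truth["clusters"]}
    ctp = len(pred_sets & true_sets)
    cluster_precision = ctp / len(pred_sets) if pred_sets else 1.0
    cluster_recall = ctp / len(true_sets) if true_sets else 1.0

    return RecoveryReport(
        assignment_precision=precision,
        assignment_recall=recall,
        n_assigned=len(pred_pairs),
        n_true_homologs=len(true_pairs),
        retention_estimate=estimate,
        retention_ci=interval,
        retention_n=n,
        cluster_precision=cluster_precision,
        cluster_recall=cluster_recall,
    )


def truth_placed_genes(truth: dict, species_code: str) -> list:
    """PlacedGene inputs for cluster detection straight from a truth table."""
    out = []
    for gid, rec in sorted(truth["genes"].items()):
        if rec["species"] != species_code or "chrom" not in rec:
            continue
        out.append(
            PlacedGene(
                gene_id=gid,
                chrom=rec["chrom"],
                start=rec["start"],
                end=rec["end"],
                rga_class=Subclass.from_label(rec["subclass"]).rga_class
                if rec["subclass"] != Subclass.NON_RGA.value
                else RGAClass.NONE,
            )
        )
    return out
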