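"""Readers and writers for every standard format the pipeline touches.

FASTA goes through Biopython, GFF3 through gffutils, tabular formats
through pandas. Internal coordinates are 1-based inclusive throughout;
BED export is the single place where conversion to 0-based half-open
happens. The packaged in-source reference tables (the 49 cloned R genes,
their per-gene homolog counts, the disease-by-gene lists, species codes)
are loaded and validated here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    ClonedRGene,
    GeneCluster,
    GeneFeature,
    HomologyHit,
    SequenceRecord,
    Subclass,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: standard 12-column BLAST tabular (outfmt 6) column order
BLAST_STD_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

#: named column-order dialects for BLAST tabular files
BLAST_DIALECTS = {
    "std": BLAST_STD_COLUMNS,
    "std+ppos": BLAST_STD_COLUMNS + ("ppos",),
    "std+ppos+qlen": BLAST_STD_COLUMNS + ("ppos", "qlen"),
}


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a protein FASTA into SequenceRecords, order preserved.

    Raises ValueError on a duplicate record id; an empty file yields an
    empty list with a logged warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def read_gff3_genes(
    path: PathLike,
    id_attribute: str = "ID",
    feature_type: str = "gene",
) -> list[GeneFeature]:
    """Extract gene features from a GFF3 file, 1-based inclusive coordinates.

    Features missing ``id_attribute`` are skipped with a warning; a file
    with no features of ``feature_type`` yields an empty list with a
    warning. Malformed coordinates (start > end) raise.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: list[GeneFeature] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        values = feat.attributes.get(id_attribute)
        if not values:
            logger.warning(
                "GFF3 feature at %s:%d-%d lacks attribute %r; skipped",
                feat.seqid,
                feat.start,
                feat.end,
                id_attribute,
            )
            continue
        if feat.start > feat.end:
            raise ValueError(
                f"GFF3 feature {values[0]}: start > end ({feat.start} > {feat.end})"
            )
        strand = feat.strand if feat.strand in {"+", "-"} else "?"
        out.append(
            GeneFeature(
                gene_id=values[0],
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
            )
        )
    if not out:
        logger.warning("no %r features found in %s", feature_type, path)
    return out


def read_blast_tabular(
    path: PathLike,
    dialect: Union[str, Sequence[str]] = "std+ppos+qlen",
) -> list[HomologyHit]:
    """Read a BLASTp tabular hit file under a declared column order.

    ``dialect`` is a named preset ("std", "std+ppos", "std+ppos+qlen") or
    an explicit column-name sequence. Similarity is taken from the percent
    positives (ppos) column when the dialect has one, else it falls back to
    percent identity with a logged warning. Row-level numeric errors report
    the 1-based line number.
    """
    columns = tuple(BLAST_DIALECTS[dialect]) if isinstance(dialect, str) else tuple(dialect)
    required = {"qseqid", "sseqid", "pident", "length", "evalue", "bitscore"}
    missing = required - set(columns)
    if missing:
        raise ValueError(f"BLAST dialect missing required column(s): {sorted(missing)}")
    has_ppos = "ppos" in columns
    if not has_ppos:
        logger.warning(
            "BLAST dialect has no ppos column; similarity falls back to identity"
        )

    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(columns):
                missing_col = columns[len(fields)]
                raise ValueError(
                    f"{path}:{lineno}: missing column {missing_col!r} "
                    f"(got {len(fields)} of {len(columns)} fields)"
                )
            row = dict(zip(columns, fields))
            try:
                evalue = float(row["evalue"])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric evalue {row['evalue']!r}"
                ) from None
            identity = float(row["pident"])
            similarity = float(row["ppos"]) if has_ppos else identity
            hits.append(
                HomologyHit(
                    query_id=row["qseqid"],
                    subject_name=row["sseqid"],
                    identity=identity,
                    alignment_length=int(row["length"]),
                    evalue=evalue,
                    bitscore=float(row["bitscore"]),
                    similarity=similarity,
                )
            )
    return hits


def write_bed(features: Iterable, path: PathLike) -> None:
    """Write gene features or clusters as BED (0-based half-open).

    The name column carries the gene/cluster id; clusters additionally get
    their type appended (``<id>|<type>``). Output is sorted by
    (chrom, start) for deterministic, track-ready files.
    """
    rows = []
    for feat in features:
        if isinstance(feat, GeneCluster):
            name = f"{feat.cluster_id}|{feat.cluster_type.value}"
        else:
            name = feat.gene_id
        rows.append((feat.chrom, feat.start - 1, feat.end, name))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for chrom, start0, end, name in rows:
            fh.write(f"{chrom}\t{start0}\t{end}\t{name}\n")


_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


def strip_transcript_suffix(protein_id: str, pattern: re.Pattern = _TRANSCRIPT_SUFFIX) -> str:
    """Map a protein/transcript id onto its gene id.

    Proteome and annotation ids drift by a trailing transcript index
    (``g1.1`` vs ``g1``); the default pattern strips one trailing
    ``.<digits>`` suffix.
    """
    return pattern.sub("", protein_id)


def attach_features(rga_records: Iterable, features: Iterable[GeneFeature]) -> int:
    """Attach gene coordinates to RGA records by id (suffix-stripped).

    Protein ids are matched to gene ids by exact string match after
    stripping the transcript suffix. Returns the number of records that
    received a feature; unmatched records keep ``feature=None``.
    """
    by_gene = {f.gene_id: f for f in features}
    n = 0
    for rec in rga_records:
        feat = by_gene.get(strip_transcript_suffix(rec.protein_id))
        if feat is not None:
            rec.feature = feat
            n += 1
    return n


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologCountRow:
    """Per-reference-gene homolog counts.

    ``diversified`` maps homolog subclass to count; ``opaque`` marks the one
    row whose diversified total is printed without a composition.
    """

    gene: str
    ref_subclass: Subclass
    retained: int
    diversified: dict
    diversified_total: int
    total: int
    opaque: bool = False


@dataclass(frozen=True)
class HomologRecord:
    """One homolog, expanded from a HomologCountRow.

    ``homolog_subclass`` is None only for records expanded from the opaque
    diversified cell (known diversified, unknown composition).
    """

    gene: str
    reference_subclass: Subclass
    homolog_subclass: Optional[Subclass]


#: printed grand-total row of the per-gene homolog table
PRINTED_TOTALS = {"retained": 1992, "diversified": 1181, "total": 3172}


@dataclass
class ReferenceTables:
    """The packaged curated reference tables, validated on load."""

    homolog_counts: list  # list[HomologCountRow], one per reference gene
    cloned_genes: dict  # name -> ClonedRGene (alias names included as keys)
    gene_disease_map: dict  # name -> frozenset of disease names
    disease_printed_totals: dict  # disease -> printed homolog total
    species_codes: dict  # species name -> 3-letter code
    anomalies: list = field(default_factory=list)

    @property
    def diseases(self) -> frozenset:
        return frozenset(self.disease_printed_totals)

    def row(self, gene: str) -> HomologCountRow:
        for r in self.homolog_counts:
            if r.gene == gene:
                return r
        raise KeyError(gene)


def _fixture_lines(name: str) -> list[str]:
    text = resources.files("cdrh.fixtures").joinpath(name).read_text()
    return [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]


def _parse_diversified(cell: str) -> dict:
    out: dict = {}
    if not cell:
        return out
    for part in cell.split(";"):
        label, count = part.rsplit(":", 1)
        out[Subclass.from_label(label)] = int(count)
    return out


def load_reference_tables() -> ReferenceTables:
    """Load and validate the packaged reference tables.

    Validation re-checks every per-gene row total (retained + diversified
    total = printed total, and the diversified breakdown sums to its
    printed total except on the opaque row). Rows where the source tables
    are internally inconsistent are recorded in ``anomalies``, never
    silently fixed.
    """
    anomalies: list[str] = []

    # cloned R genes
    lines = _fixture_lines("cloned_genes.tsv")
    header = lines[0].split("\t")
    assert header[0] == "gene"
    cloned: dict = {}
    for ln in lines[1:]:
        f = (ln.split("\t") + [""] * 5)[:5]
        gene = ClonedRGene(
            name=f[0],
            subclass=Subclass.from_label(f[1]),
            accession=f[2],
            alias=f[3],
            pathogens=frozenset(p for p in f[4].split(";") if p),
        )
        if gene.name in cloned:
            raise ValueError(f"duplicate cloned gene name {gene.name!r}")
        cloned[gene.name] = gene
        if gene.alias:
            cloned[gene.alias] = gene

    # disease-by-gene map
    disease_map: dict = {}
    for ln in _fixture_lines("gene_diseases.tsv")[1:]:
        f = ln.split("\t")
        name = f[0]
        diseases = frozenset(d for d in (f[1].split(";") if len(f) > 1 else []) if d)
        disease_map[name] = diseases

    # printed per-disease totals
    disease_totals: dict = {}
    for ln in _fixture_lines("disease_totals.tsv")[1:]:
        disease, total = ln.split("\t")
        disease_totals[disease] = int(total)

    # species codes
    species_codes: dict = {}
    for ln in _fixture_lines("species_codes.tsv")[1:]:
        species, code = ln.split("\t")
        species_codes[species] = code

    # per-gene homolog counts
    rows: list[HomologCountRow] = []
    for ln in _fixture_lines("homolog_counts.tsv")[1:]:
        f = ln.split("\t")
        row = HomologCountRow(
            gene=f[0],
            ref_subclass=Subclass.from_label(f[1]),
            retained=int(f[2]),
            diversified=_parse_diversified(f[3]),
            diversified_total=int(f[4]),
            total=int(f[5]),
            opaque=bool(int(f[6])),
        )
        if row.retained + row.diversified_total != row.total:
            raise ValueError(
                f"homolog-count row {row.gene}: retained ({row.retained}) + "
                f"diversified ({row.diversified_total}) != total ({row.total})"
            )
        breakdown = sum(row.diversified.values())
        if row.opaque:
            anomalies.append(
                f"{row.gene}: diversified total {row.diversified_total} printed "
                "with no subclass composition (kept opaque)"
            )
        elif breakdown != row.diversified_total:
            raise ValueError(
                f"homolog-count row {row.gene}: diversified breakdown sums to "
                f"{breakdown}, printed total is {row.diversified_total}"
            )
        rows.append(row)

    distinct_genes = {r.gene for r in rows}
    if len(distinct_genes) != 49 or len(rows) != 49:
        raise ValueError(f"expected 49 reference genes, found {len(rows)}")
    missing = distinct_genes - set(cloned)
    if missing:
        raise ValueError(f"homolog-count genes missing from cloned-gene table: {missing}")
    unknown_diseases = set().union(*disease_map.values()) - set(disease_totals)
    if unknown_diseases:
        raise ValueError(f"diseases outside the 11 curated ones: {unknown_diseases}")

    # grand-total bookkeeping against the printed total row
    retained_sum = sum(r.retained for r in rows)
    diversified_sum = sum(r.diversified_total for r in rows)
    if retained_sum != PRINTED_TOTALS["retained"]:
        raise ValueError(
            f"retained column sums to {retained_sum}, printed {PRINTED_TOTALS['retained']}"
        )
    if diversified_sum != PRINTED_TOTALS["diversified"]:
        anomalies.append(
            f"diversified column sums to {diversified_sum} but the printed "
            f"grand total is {PRINTED_TOTALS['diversified']} (one-unit "
            "source-table inconsistency; per-row values are authoritative)"
        )

    # diseases whose gene sums disagree with the printed per-disease totals
    gene_total = {r.gene: r.total for r in rows}
    for disease in sorted(disease_totals):
        gene_sum = sum(
            gene_total[g] for g, ds in disease_map.items() if disease in ds
        )
        if gene_sum != disease_totals[disease]:
            anomalies.append(
                f"{disease}: printed total {disease_totals[disease]} vs "
                f"per-gene sum {gene_sum} (both reported, neither preferred)"
            )

    return ReferenceTables(
        homolog_counts=rows,
        cloned_genes=cloned,
        gene_disease_map=disease_map,
        disease_printed_totals=disease_totals,
        species_codes=species_codes,
        anomalies=anomalies,
    )


def expand_homolog_counts(fixture: ReferenceTables) -> list[HomologRecord]:
    """Expand the per-gene homolog counts to one record per homolog.

    Retained homologs get the reference's own subclass; diversified
    homologs get their printed subclass; the opaque diversified cell
    expands to records with ``homolog_subclass=None``.
    """
    records: list[HomologRecord] = []
    for row in fixture.homolog_counts:
        records.extend(
            HomologRecord(row.gene, row.ref_subclass, row.ref_subclass)
            for _ in range(row.retained)
        )
        for subclass, count in row.diversified.items():
            records.extend(
                HomologRecord(row.gene, row.ref_subclass, subclass)
                for _ in range(count)
            )
        if row.opaque:
            records.extend(
                HomologRecord(row.gene, row.ref_subclass, None)
                for _ in range(row.diversified_total)
            )
    return records
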