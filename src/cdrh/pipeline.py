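"""End-to-end driver: files in, assignments and clusters out.

Chains the pipeline stages over one directory of inputs (as emitted by
the synthetic generator or produced externally): domain table ->
RGA classification -> hit filtering -> best-reference assignment ->
disease mapping -> evolution annotation -> per-species cluster detection.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Optional

from .cdrh_identifier import (
    DEFAULT_FILTER,
    FilterConfig,
    assign_best_reference,
    filter_hits,
    map_diseases,
)
from .cluster_detector import (
    DEFAULT_CLUSTER_CONFIG,
    ClusterConfig,
    find_clusters,
    placed_genes_from_assignments,
)
from .domain_evolution import annotate_evolution
from .formats_io import (
    ReferenceTables,
    attach_features,
    load_reference_tables,
    read_blast_tabular,
    read_gff3_genes,
)
from .rga_classifier import DEFAULT_CONFIG, ClassifierConfig, classify_proteome, read_domain_table


def run_pipeline(
    in_dir,
    species_of_protein=None,
    fixture: Optional[ReferenceTables] = None,
    classifier_config: ClassifierConfig = DEFAULT_CONFIG,
    filter_config: FilterConfig = DEFAULT_FILTER,
    cluster_config: ClusterConfig = DEFAULT_CLUSTER_CONFIG,
    blast_dialect: str = "std+ppos+qlen",
):
    """Run every stage over ``in_dir`` (domains.tsv, hits.tsv, genes.gff3).

    ``species_of_protein`` maps a protein id to its species code; by
    default the prefix before the first underscore is used. Returns
    (assignments, clusters_by_species, evolution_summary).
    """
    in_dir = Path(in_dir)
    if fixture is None:
        fixture = load_reference_tables()
    if species_of_protein is None:
        species_of_protein = lambda pid: pid.split("_", 1)[0]  # noqa: E731

    annotations = read_domain_table(in_dir / "domains.tsv")
    by_species = defaultdict(list)
    for ann in annotations:
        by_species[species_of_protein(ann.protein_id)].append(ann)
    rgas = []
    for code in sorted(by_species):
        rgas.extend(classify_proteome(by_species[code], code, classifier_config))
    rga_table = {r.protein_id: r for r in rgas}

    hits = read_blast_tabular(in_dir / "hits.tsv", dialect=blast_dialect)
    passing = filter_hits(hits, filter_config)
    assignments = assign_best_reference(passing, rga_table, fixture.cloned_genes)
    assignments = map_diseases(assignments, fixture)
    assignments, evolution_summary = annotate_evolution(assignments)

    gff = in_dir / "genes.gff3"
    clusters_by_species = {}
    if gff.exists():
        features = read_gff3_genes(gff)
        attach_features((a.rga for a in assignments), features)
        per_species = defaultdict(list)
        for a in assignments:
            per_species[a.rga.species_code].append(a)
        for code in sorted(per_species):
            placed = placed_genes_from_assignments(per_species[code])
            clusters_by_species[code] = find_clusters(
                placed, cluster_config, id_prefix=f"{code}_GC"
            )
    return assignments, clusters_by_species, evolution_summary
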