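"""Classify the synthetic proteomes into RGA subclasses.

Reads the domain table from the simulation directory, runs the
architecture decision table per species, writes per-species subclass
counts to results/rga_counts.csv and the full RGA table to
scratch/rga.tsv, and prints the class breakdown.
"""

import argparse
from collections import defaultdict
from pathlib import Path

import pandas as pd

from cdrh.rga_classifier import classify_proteome, read_domain_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("scratch/sim"))
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    annotations = read_domain_table(args.sim / "domains.tsv")
    by_species = defaultdict(list)
    for ann in annotations:
        by_species[ann.protein_id.split("_", 1)[0]].append(ann)

    rows = []
    rgas = []
    for code in sorted(by_species):
        records = classify_proteome(by_species[code], code)
        rgas.extend(records)
        for r in records:
            rows.append(
                {"species": code, "subclass": r.subclass.value, "class": r.rga_class.value}
            )
    frame = pd.DataFrame(rows)
    counts = (
        frame.groupby(["species", "class"]).size().unstack(fill_value=0).reset_index()
    )
    counts.to_csv(args.results / "rga_counts.csv", index=False)
    pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in rgas],
            "species": [r.species_code for r in rgas],
            "subclass": [r.subclass.value for r in rgas],
            "class": [r.rga_class.value for r in rgas],
            "domains": [";".join(sorted(d.value for d in r.domain_set)) for r in rgas],
        }
    ).to_csv(args.sim.parent / "rga.tsv", sep="\t", index=False)

    print(f"{len(rgas)} RGAs classified across {len(by_species)} proteomes")
    print(counts.to_string(index=False))
    print(f"per-species counts -> {args.results / 'rga_counts.csv'}")


if __name__ == "__main__":
    main()
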