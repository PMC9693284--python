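"""Domain retention and diversification of the synthetic CDRHs.

Annotates every assignment with a retention/diversification call, writes
the per-reference-subclass summary (results/evolution_summary.csv) and
the per-reference-gene retention matrix (results/retention_matrix.csv),
and compares the estimated retention fraction against the planted
retention probability with its exact binomial 95% CI.
"""

import argparse
import json
from pathlib import Path

from cdrh.formats_io import load_reference_tables
from cdrh.pipeline import run_pipeline
from cdrh.reporting import retention_matrix
from cdrh.synthetic import estimate_recovery


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("scratch/sim"))
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    fixture = load_reference_tables()
    assignments, clusters, summary = run_pipeline(args.sim, fixture=fixture)
    summary.to_csv(args.results / "evolution_summary.csv", index=False)
    matrix = retention_matrix(assignments, fixture)
    matrix.to_csv(args.results / "retention_matrix.csv", index=False)

    truth = json.loads((args.sim / "truth.json").read_text())
    all_clusters = [c for cs in clusters.values() for c in cs]
    report = estimate_recovery(assignments, all_clusters, truth)

    retained = summary.loc[summary.status == "retained", "count"].sum()
    total = summary["count"].sum()
    print(f"{retained}/{total} CDRHs retained their reference's RGA domain structure")
    print(
        f"retention estimate {report.retention_estimate:.4f} "
        f"(95% CI {report.retention_ci[0]:.4f}-{report.retention_ci[1]:.4f}, "
        f"n={report.retention_n}) vs planted "
        f"{truth['config']['retention_prob']}"
    )
    print(
        f"assignment precision {report.assignment_precision:.3f}, "
        f"recall {report.assignment_recall:.3f} over "
        f"{report.n_true_homologs} planted homologs"
    )
    print(f"tables -> {args.results}/evolution_summary.csv, retention_matrix.csv")


if __name__ == "__main__":
    main()
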