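#!/usr/bin/env python
"""Nodal group statistics: which regions differ between patients and controls?

Runs the age/sex-adjusted group test on every node's AUC for degree,
betweenness and nodal efficiency, corrects within each metric family by
BH-FDR, and writes the abnormal-node report that the dynamic-connectivity
stage takes as its ROI list.

Outputs: results/analysis/nodal_auc_tests.tsv, abnormal_nodes.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fcdec import RunConfig, default_atlas
from fcdec.group_stats import abnormal_node_report, nodal_auc_tests
from fcdec.io_config import read_manifest


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--tables", type=Path, default=Path("results/analysis"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    config = RunConfig()
    atlas = default_atlas()
    manifest = read_manifest(args.data / "manifest.tsv")
    auc_tables = {}
    for metric in ("degree", "betweenness", "efficiency"):
        df = pd.read_csv(args.tables / f"auc_{metric}.tsv", sep="\t", index_col="subject_id")
        df.columns = df.columns.astype(int)
        auc_tables[metric] = df

    tests = nodal_auc_tests(auc_tables, manifest)
    tests["roi"] = [atlas.abbreviations[n - 1] for n in tests["node"]]
    tests.to_csv(args.out / "nodal_auc_tests.tsv", sep="\t", index=False)
    report = abnormal_node_report(tests, alpha=config.alpha)
    report.to_csv(args.out / "abnormal_nodes.tsv", sep="\t", index=False)

    if report.empty:
        print("no node survives FDR at alpha=0.05")
        return
    print(f"{report['node'].nunique()} abnormal regions (FDR p < {config.alpha}):")
    for node in sorted(report["node"].unique()):
        sub = report[report.node == node]
        mets = ", ".join(f"{r.metric} ({r.direction}, p_fdr={r.p_fdr:.3g})"
                         for r in sub.itertuples())
        print(f"  {atlas.abbreviations[node - 1]:>10}: {mets}")


if __name__ == "__main__":
    main()
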