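#!/usr/bin/env python
"""Biostimulation impact factors (IF_Pc) and their PCA.

IF_Pc = A_Pc / A_C compares each response (microbial count or enzyme
activity) in biostimulated soil against a baseline: the same dose without
the amendment ("paired", the default) or clean biostimulated soil
("control-soil", the literal convention).  A correlation-matrix PCA of each
IF matrix (treatment cells as cases, responses as variables) summarizes
which responses the mussel-shell amendment moves together.
"""

import argparse
from pathlib import Path

from soiltox.group_stats import pca_if
from soiltox.indices import compute_if_matrix
from soiltox.io import read_activity_table, read_colony_series
from soiltox.pipeline import _split_pc, microbial_count_tables

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

count_tables = microbial_count_tables(read_colony_series(args.data / "colony_counts.csv"))
enzyme_tables = [read_activity_table(p) for p in sorted((args.data / "enzymes").glob("*.csv"))]

for label, tables in (("counts", count_tables), ("enzymes", enzyme_tables)):
    with_pc, without_pc = _split_pc(tables)
    for mode in ("paired", "control-soil"):
        matrix = compute_if_matrix(with_pc, without_pc, baseline_mode=mode)
        stem = f"if_{label}_{mode}"
        flat = matrix.values.copy()
        flat.columns = [f"{dose:g}:{day}" for dose, day in flat.columns]
        flat.to_csv(args.out / f"{stem}.csv", index_label="response")
        report = pca_if(matrix, standardized=True)
        report.loadings.to_csv(args.out / f"{stem}_loadings.csv", index_label="variable")
        report.scores.to_csv(args.out / f"{stem}_scores.csv", index_label="case")
        pc1, pc2 = report.explained_pct[:2]
        stimulated = (matrix.values.to_numpy() > 1).mean()
        print(f"{label:<8} {mode:<13} PC1 {pc1:5.1f}%  PC2 {pc2:5.1f}%  "
              f"(cells with IF > 1: {100 * stimulated:.0f}%)")
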