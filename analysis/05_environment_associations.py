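#!/usr/bin/env python
"""Co-occurrence networks and family-environment correlation heatmaps.

Builds the thresholded Spearman network (|rho| > 0.3, p < 0.05, families
above 1% mean abundance) separately for the one-month infants and the adults,
and the family × environment correlation table for the longitudinal cohort.
Expected outcome: a negative Bifidobacteriaceae-Enterobacteriaceae edge in
infants, and acetate up / pH down / residual oligosaccharide down with
Bifidobacteriaceae abundance.
"""

import argparse
from pathlib import Path

import pandas as pd

from infantgut.association import (
    build_network,
    correlation_heatmap_table,
    export_graph,
)
from infantgut.profiles import read_abundance_table, read_environment, read_metadata


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/association"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # networks per life stage: infants vs adults of the survey
    table = read_abundance_table(args.datadir / "survey_abundance.tsv")
    meta = read_metadata(args.datadir / "survey_metadata.tsv")
    for stage, cohorts in (("infant", {"infant_1mo"}), ("adult", {"adult"})):
        ids = meta.data.loc[meta.data["cohort"].isin(cohorts), "sample_id"]
        g = build_network(table, sample_ids=list(ids))
        export_graph(g, args.outdir / f"{stage}_network.graphml", "graphml")
        export_graph(g, args.outdir / f"{stage}_network_edges.tsv", "edge-tsv")
        neg = sum(d["sign"] == "-" for *_, d in g.edges(data=True))
        print(f"{stage} network: {g.number_of_nodes()} nodes, "
              f"{g.number_of_edges()} edges ({neg} negative)")

    # family x environment heatmap on the longitudinal cohort
    table = read_abundance_table(args.datadir / "longitudinal_abundance.tsv")
    env = read_environment(args.datadir / "longitudinal_environment.tsv")
    cells = correlation_heatmap_table(table, env, min_mean=0.01)
    cells.to_csv(args.outdir / "environment_heatmap.tsv", sep="\t",
                 index=False, float_format="%.6g")
    bif = cells[cells["family"] == "Bifidobacteriaceae"].set_index("variable")
    print("Bifidobacteriaceae correlations: "
          + ", ".join(f"{v} rho={bif.loc[v, 'rho']:.2f}"
                      for v in ("acetate", "pH", "oligosaccharide")))


if __name__ == "__main__":
    main()
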