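#!/usr/bin/env python
"""Characterize the clusters: which families and environment variables differ.

For each cohort: pairwise two-sided Mann-Whitney U tests between clusters on
every family abundance and environment variable (Bonferroni family = cluster
pairs per variable), compact letter displays, and box-plot summaries.
Expected outcome: each cluster's dominant family separates it from the other
clusters (letters a/b/c), and acetate/pH separate the
Bifidobacteriaceae-dominant cluster.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from infantgut.profiles import read_abundance_table, read_environment
from infantgut.stats import box_summary, compare_clusters, comparisons_to_frame


def characterize(name: str, args) -> None:
    table = read_abundance_table(args.datadir / f"{name}_abundance.tsv")
    env = read_environment(args.datadir / f"{name}_environment.tsv")
    payload = json.loads(
        (args.typingdir / f"{name}_clustering.json").read_text()
    )
    labels = pd.Series(payload["assignment"]).loc[table.sample_ids]
    env_df = env.data.set_index("sample_id").loc[table.sample_ids]
    values = pd.concat([table.data, env_df], axis=1)

    comparisons, letters = compare_clusters(values, labels, alpha=0.05)
    args.outdir.mkdir(parents=True, exist_ok=True)
    comparisons_to_frame(comparisons).to_csv(
        args.outdir / f"{name}_comparisons.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    (args.outdir / f"{name}_letters.json").write_text(
        json.dumps({v: {str(k): s for k, s in m.items()}
                    for v, m in letters.items()}, indent=2)
    )

    summaries = []
    for var in values.columns:
        for cluster in sorted(labels.unique()):
            s = box_summary(values.loc[labels == cluster, var].dropna())
            summaries.append(
                {"variable": var, "cluster": cluster, "median": s.median,
                 "q1": s.q1, "q3": s.q3, "whisker_low": s.whisker_low,
                 "whisker_high": s.whisker_high, "n_outliers": len(s.outliers)}
            )
    pd.DataFrame(summaries).to_csv(
        args.outdir / f"{name}_box_summaries.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    n_sig = sum(c.significant for c in comparisons if c.testable)
    print(f"{name}: {n_sig}/{len(comparisons)} pairwise comparisons "
          f"significant at Bonferroni-adjusted p < 0.05")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--typingdir", type=Path, default=Path("results/typing"))
    parser.add_argument("--outdir", type=Path, default=Path("results/characterization"))
    args = parser.parse_args()
    for name in ("longitudinal", "survey"):
        characterize(name, args)


if __name__ == "__main__":
    main()
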