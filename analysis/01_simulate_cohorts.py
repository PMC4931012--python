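#!/usr/bin/env python
"""Generate the two synthetic cohorts every downstream analysis consumes.

Writes, under results/data/:
  longitudinal_*  — 12 infants sampled ~17 times during the first month
                    (3 composition regimes, forward-biased daily transitions,
                    environment variables coupled to Bifidobacteriaceae);
  survey_*        — a cross-sectional one-month survey: 18 infants with
                    Bifidobacteriaceae-dominant and 9 with
                    Enterobacteriaceae-dominant microbiota, plus 22 adults.

Ground-truth regime labels are kept as sidecar tables for recovery checks.
"""

import argparse
from pathlib import Path

from infantgut.profiles import write_abundance_table
from infantgut.simulate import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_survey,
    one_month_survey_config,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path,
                        default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table, meta, env, truth = generate_cohort(
        SyntheticCohortConfig(n_subjects=12, seed=args.seed)
    )
    write_abundance_table(table, args.outdir / "longitudinal_abundance.tsv")
    meta.data.to_csv(args.outdir / "longitudinal_metadata.tsv", sep="\t", index=False)
    env.data.to_csv(args.outdir / "longitudinal_environment.tsv", sep="\t",
                    index=False, float_format="%.12g")
    truth.to_csv(args.outdir / "longitudinal_truth.tsv", sep="\t", index=False)
    print(f"longitudinal cohort: {table.n_samples} samples, "
          f"{len(truth['subject_id'].unique())} subjects")

    cfg = one_month_survey_config(n_cluster_b=18, n_cluster_e=9, n_adults=22,
                                  seed=args.seed + 1)
    table, meta, env, truth = generate_survey(cfg)
    write_abundance_table(table, args.outdir / "survey_abundance.tsv")
    meta.data.to_csv(args.outdir / "survey_metadata.tsv", sep="\t", index=False)
    env.data.to_csv(args.outdir / "survey_environment.tsv", sep="\t",
                    index=False, float_format="%.12g")
    truth.to_csv(args.outdir / "survey_truth.tsv", sep="\t", index=False)
    print(f"one-month survey: {table.n_samples} samples "
          f"(27 infants + 22 adults)")


if __name__ == "__main__":
    main()
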