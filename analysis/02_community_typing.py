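#!/usr/bin/env python
"""Type the communities: sqrt-JSD distances, cluster-number voting, PAM, PCoA.

For each cohort written by 01_simulate_cohorts.py this computes the pairwise
sqrt Jensen-Shannon distance matrix, votes on the cluster number by CH-scored
PAM over random 80% subsamples, fits the final medoid partition at the modal
k, and records the first two principal coordinates.  Expected outcome at the
default study conditions: modal k = 3 in both cohorts (the three infant
regimes; or two infant clusters plus the adult cluster).
"""

import argparse
import json
from pathlib import Path

from infantgut.community import estimate_k, hclust_complete, jsd_matrix, pam
from infantgut.profiles import read_abundance_table


def type_cohort(name: str, datadir: Path, outdir: Path, seed: int,
                trials: int) -> None:
    table = read_abundance_table(datadir / f"{name}_abundance.tsv")
    dist = jsd_matrix(table)
    vote = estimate_k(dist, range(2, 9), trials=trials,
                      subsample_fraction=0.8, seed=seed)
    solution = pam(dist, vote.optimal_k)
    from infantgut.community import pcoa

    ordination = pcoa(dist, n_axes=2)
    outdir.mkdir(parents=True, exist_ok=True)
    dist.to_tsv(outdir / f"{name}_distances.tsv")
    ordination.to_frame().to_csv(outdir / f"{name}_pcoa.tsv", sep="\t",
                                 float_format="%.12g")
    order = hclust_complete(dist).leaf_order
    (outdir / f"{name}_heatmap_order.txt").write_text("\n".join(order) + "\n")
    payload = {
        "optimal_k": vote.optimal_k,
        "votes": vote.votes,
        "trials": vote.trials,
        "subsample_fraction": vote.subsample_fraction,
        "seed": seed,
        "medoid_ids": solution.medoid_ids,
        "assignment": solution.assignment,
        "total_cost": solution.total_cost,
        "ch": solution.ch,
    }
    (outdir / f"{name}_clustering.json").write_text(json.dumps(payload, indent=2))
    print(f"{name}: modal k = {vote.optimal_k}, votes {vote.votes}, "
          f"cluster sizes {solution.sizes()}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--trials", type=int, default=300)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/typing"))
    args = parser.parse_args()
    for name in ("longitudinal", "survey"):
        type_cohort(name, args.datadir, args.outdir, args.seed, args.trials)


if __name__ == "__main__":
    main()
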