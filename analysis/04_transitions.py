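#!/usr/bin/env python
"""Longitudinal dynamics: state series and directional transition counts.

Maps each longitudinal sample to its community state (cluster named by its
dominant mean family), counts transitions between consecutive observed
samples per subject, and measures the forward fraction along
Staphylococcaceae < Enterobacteriaceae < Bifidobacteriaceae.  Expected
outcome at the study conditions: transitions run overwhelmingly forward
(fraction well above 0.5) — reversals are rare.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from infantgut.community import ClusterSolution
from infantgut.dynamics import (
    assign_states,
    directionality,
    series_to_grid,
    transition_counts,
)
from infantgut.profiles import read_abundance_table, read_metadata

ORDER = ["Staphylococcaceae", "Enterobacteriaceae", "Bifidobacteriaceae"]
ABBREV = {"Staphylococcaceae": "S", "Enterobacteriaceae": "E",
          "Bifidobacteriaceae": "B"}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--typingdir", type=Path, default=Path("results/typing"))
    parser.add_argument("--outdir", type=Path, default=Path("results/transitions"))
    args = parser.parse_args()

    table = read_abundance_table(args.datadir / "longitudinal_abundance.tsv")
    meta = read_metadata(args.datadir / "longitudinal_metadata.tsv")
    payload = json.loads(
        (args.typingdir / "longitudinal_clustering.json").read_text()
    )
    assignment = {s: int(c) for s, c in payload["assignment"].items()}
    solution = ClusterSolution(
        k=payload["optimal_k"],
        medoid_ids=payload["medoid_ids"],
        assignment=assignment,
        labels=np.array([assignment[s] for s in table.sample_ids]),
        total_cost=payload["total_cost"],
        ch=payload.get("ch"),
    )
    series = assign_states(table, meta, solution)
    matrix = transition_counts(series)
    frac, defined = directionality(matrix, ORDER)

    args.outdir.mkdir(parents=True, exist_ok=True)
    matrix.counts.to_csv(args.outdir / "transition_counts.tsv", sep="\t")
    series_to_grid(series, abbrev=ABBREV).to_csv(
        args.outdir / "state_series.tsv", sep="\t"
    )
    (args.outdir / "directionality.json").write_text(json.dumps({
        "forward_fraction": frac if defined else None,
        "defined": defined,
        "total_transitions": matrix.total,
        "order": ORDER,
    }, indent=2))
    off = matrix.total - int(np.diag(matrix.counts.to_numpy()).sum())
    print(f"{matrix.total} consecutive-sample pairs, {off} state changes; "
          f"forward fraction {frac:.3f}" if defined
          else "no state changes observed")


if __name__ == "__main__":
    main()
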