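"""Strain growth phenotyping and the gene presence/absence concordance screen.

Bifidobacterial strains are classified as HMO growers or non-growers from
their saturating OD600 in HMO medium (grower above 0.7, non-grower below 0.3,
indeterminate between).  Ortholog-group membership (OrthoMCL "groups" text
format) becomes a strains × homologous-groups binary matrix, and the screen
scans every group for concordance between gene presence and the growth
phenotype, tolerating a bounded number of exception strains.  Applied to the
packaged 29-strain reference panel this recovers a single discriminating
group — the substrate-binding protein (SBP) of the fucosyllactose ABC
transporter — with one exception strain (*B. bifidum* BI-14, which grows
despite lacking the transporter thanks to extracellular fucosidases).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "GrowthCurve",
    "ConcordanceHit",
    "classify_growth",
    "read_growth_curves",
    "read_ortholog_groups",
    "write_ortholog_groups",
    "concordance_screen",
    "reference_panel",
]

GROWER = "grower"
NON_GROWER = "non_grower"
INDETERMINATE = "indeterminate"

PRESENCE_POSITIVE = "presence_with_positive"
PRESENCE_NEGATIVE = "presence_with_negative"


@dataclass
class GrowthCurve:
    """One replicate's OD600 time series for a strain."""

    strain_id: str
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times not strictly increasing for {self.strain_id}")
        if np.any(self.od < 0):
            raise ValueError(f"negative OD for {self.strain_id}")


@dataclass
class ConcordanceHit:
    """One homologous group's agreement with the phenotype."""

    group_id: str
    orientation: str
    n_match: int
    exceptions: list[tuple[str, str]] = field(default_factory=list)
    # (strain_id, "present_but_non_grower" | "absent_but_grower" and mirror)

    @property
    def n_exceptions(self) -> int:
        return len(self.exceptions)


def classify_growth(
    curves: Sequence[GrowthCurve],
    high: float = 0.7,
    low: float = 0.3,
    smooth_window: int = 3,
) -> tuple[str, float]:
    """Phenotype label and saturating OD for one strain's replicate curves.

    Replicates are averaged pointwise (they must share a time grid), the
    averaged curve is median-smoothed (window ``smooth_window``, guarding
    against single-well spikes), and the saturating OD is the smoothed
    maximum.  Labels: grower if above ``high``, non-grower if below ``low``,
    otherwise indeterminate.
    """
    if high <= low:
        raise ValueError(f"high ({high}) must exceed low ({low})")
    if not curves:
        raise ValueError("no curves supplied")
    t0 = curves[0].times
    if len(t0) < 3:
        raise ValueError("need at least 3 time points")
    for c in curves[1:]:
        if not np.array_equal(c.times, t0):
            raise ValueError("replicates must share a time grid")
    mean_od = np.mean([c.od for c in curves], axis=0)
    if smooth_window > 1:
        # edge-replicated padding: zero padding would clip a final plateau
        mean_od = median_filter(mean_od, size=smooth_window, mode="nearest")
    sat = float(mean_od.max())
    if sat > high:
        return GROWER, sat
    if sat < low:
        return NON_GROWER, sat
    return INDETERMINATE, sat


def read_growth_curves(path: str | Path) -> dict[str, list[GrowthCurve]]:
    """Long-format CSV (strain, replicate, time_h, od600) -> curves per strain."""
    df = pd.read_csv(path)
    required = {"strain", "replicate", "time_h", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV missing columns: {sorted(missing)}")
    out: dict[str, list[GrowthCurve]] = {}
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.setdefault(str(strain), []).append(
            GrowthCurve(str(strain), grp["time_h"].to_numpy(),
                        grp["od600"].to_numpy(), int(rep))
        )
    return out


def _default_strain_parser(token: str) -> str:
    return token.split("|", 1)[0]


def read_ortholog_groups(
    path: str | Path,
    panel: Sequence[str] | None = None,
    strain_parser: Callable[[str], str] = _default_strain_parser,
    keep_counts: bool = False,
) -> pd.DataFrame:
    """Parse an OrthoMCL groups file into a strains × groups presence matrix.

    Format: one group per line, ``GROUP_ID: strain|gene strain|gene ...``.
    Presence means the strain contributes at least one gene; with
    ``keep_counts`` the per-strain gene counts are retained instead.  Strains
    in ``panel`` missing from every group get all-zero rows; strains found in
    the file but absent from the declared panel trigger a warning.
    """
    path = Path(path)
    groups: dict[str, dict[str, int]] = {}
    seen_strains: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path.name}:{lineno}: missing 'GROUP_ID:' prefix")
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            if not gid:
                raise ValueError(f"{path.name}:{lineno}: empty group id")
            members: dict[str, int] = {}
            for token in rest.split():
                strain = strain_parser(token)
                if not strain:
                    raise ValueError(f"{path.name}:{lineno}: unparseable token {token!r}")
                members[strain] = members.get(strain, 0) + 1
                seen_strains.add(strain)
            groups[gid] = members
    if not groups:
        warnings.warn(f"{path.name}: no groups parsed", stacklevel=2)
    if panel is not None:
        extra = seen_strains - set(panel)
        if extra:
            warnings.warn(f"strains outside declared panel: {sorted(extra)}", stacklevel=2)
        strains = list(panel)
    else:
        strains = sorted(seen_strains)
    mat = pd.DataFrame(0, index=strains, columns=list(groups), dtype=int)
    for gid, members in groups.items():
        for strain, count in members.items():
            if strain in mat.index:
                mat.loc[strain, gid] = count if keep_counts else 1
    mat.index.name = "strain_id"
    return mat


def write_ortholog_groups(matrix: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_ortholog_groups` (presence -> one synthetic gene)."""
    with open(path, "w") as fh:
        for gid in matrix.columns:
            members = [
                f"{strain}|g" for strain in matrix.index if matrix.loc[strain, gid]
            ]
            fh.write(f"{gid}: {' '.join(members)}\n")


def concordance_screen(
    presence: pd.DataFrame,
    phenotype: Mapping[str, str] | pd.Series,
    max_exceptions: int = 1,
    orientations: str = "both",
) -> list[ConcordanceHit]:
    """Scan every homologous group for concordance with the growth phenotype.

    For each group, count strains where gene presence equals the grower
    phenotype (presence-with-positive orientation) and, when
    ``orientations="both"``, where absence equals the grower phenotype.
    Groups with at most ``max_exceptions`` mismatching strains are returned,
    sorted by (exception count, group id); exception strains are listed with
    their mismatch direction.  Indeterminate strains are excluded up front.
    Constant (all-present or all-absent) groups can never discriminate and
    are never reported as hits unless a phenotype class is that small.
    """
    if orientations not in ("both", PRESENCE_POSITIVE):
        raise ValueError(f"unknown orientations {orientations!r}")
    pheno = pd.Series(phenotype)
    pheno = pheno[pheno != INDETERMINATE]
    unknown = set(pheno.unique()) - {GROWER, NON_GROWER}
    if unknown:
        raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")
    strains = [s for s in presence.index if s in pheno.index]
    y = (pheno.loc[strains] == GROWER).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 strains in each phenotype class")
    x = presence.loc[strains].to_numpy() > 0  # n_strains x n_groups
    n = len(strains)

    hits: list[ConcordanceHit] = []
    orients = [PRESENCE_POSITIVE]
    if orientations == "both":
        orients.append(PRESENCE_NEGATIVE)
    for orient in orients:
        target = y if orient == PRESENCE_POSITIVE else ~y
        mismatch = x != target[:, None]  # strain disagrees with orientation
        n_exc = mismatch.sum(axis=0)
        for j in np.flatnonzero(n_exc <= max_exceptions):
            exceptions = []
            for i in np.flatnonzero(mismatch[:, j]):
                if x[i, j]:
                    direction = (
                        "present_but_non_grower"
                        if orient == PRESENCE_POSITIVE
                        else "present_but_grower"
                    )
                else:
                    direction = (
                        "absent_but_grower"
                        if orient == PRESENCE_POSITIVE
                        else "absent_but_non_grower"
                    )
                exceptions.append((strains[i], direction))
            hits.append(
                ConcordanceHit(
                    group_id=str(presence.columns[j]),
                    orientation=orient,
                    n_match=int(n - n_exc[j]),
                    exceptions=exceptions,
                )
            )
    hits.sort(key=lambda h: (h.n_exceptions, h.group_id, h.orientation))
    return hits


def reference_panel() -> tuple[pd.DataFrame, pd.Series]:
    """The packaged 29-strain bifidobacterial panel.

    Strains isolated from the infant cohort with their HMO growth phenotype
    and the presence flags of the two fucosidase families (GH29, GH95) and
    the fucosyllactose ABC-transporter SBP gene group.

    Returns (presence matrix over columns GH29/GH95/FL_SBP, phenotype series).
    """
    with resources.files("infantgut.data").joinpath(
        "reference_strain_panel.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df.set_index("strain_id")
    presence = df[["GH29", "GH95", "FL_SBP"]].astype(int)
    phenotype = df["hmo_growth"].astype(str)
    phenotype.name = "hmo_growth"
    return presence, phenotype
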