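"""Relative-abundance tables, sample metadata and gut-environment variables.

The central object of the pipeline is a samples × taxa table of family-level
relative abundances.  Input tables may carry read counts, percentages or
fractions; they are always renormalized row-wise and stored as fractions, so
every row is a probability vector over taxa.  Metadata (subject, day of life,
cohort) and environment variables (pH, organic acids, residual
oligosaccharides, cell counts) are kept in separate tables keyed by sample id
and joined on demand.

Missing environment values are kept as NaN, never coerced to zero: zero is a
valid concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "EnvironmentTable",
    "AlignedView",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "read_environment",
    "filter_prevalent",
    "align",
]

COHORTS = ("infant_longitudinal", "infant_1mo", "adult")

#: row sums must match 1 this closely after normalization
_ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """Samples × taxa relative-abundance matrix.

    Parameters
    ----------
    data
        DataFrame with unique sample ids as index and unique taxon (family)
        names as columns.  When ``normalized`` is True every row sums to 1
        within 1e-9 and all entries lie in [0, 1].
    normalized
        False only for derived views (e.g. after a prevalence filter, which
        deliberately does not renormalize the surviving taxa).
    """

    data: pd.DataFrame
    normalized: bool = True

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = df.index[~np.isfinite(values).all(axis=1)][0]
            raise ValidationError(f"non-finite abundance in sample {bad!r}")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if self.normalized:
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if off.any():
                bad = df.index[off][0]
                raise ValidationError(
                    f"row for sample {bad!r} sums to {sums[off][0]:.6g}, expected 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[list(sample_ids)], normalized=self.normalized)


@dataclass
class SampleMetadata:
    """Per-sample metadata: subject, day of life, cohort, free-form labels.

    ``day`` may be missing (adults); when present it must be a non-negative
    integer.  ``cohort`` must be one of :data:`COHORTS`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"sample_id", "subject_id", "cohort"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        bad_cohort = set(df["cohort"].dropna()) - set(COHORTS)
        if bad_cohort:
            raise ValidationError(f"unknown cohort labels: {sorted(bad_cohort)}")
        if "day" in df.columns:
            days = pd.to_numeric(df["day"], errors="coerce")
            present = days.notna()
            if (days[present] < 0).any():
                raise ValidationError("negative day of life in metadata")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def for_samples(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        idx = self.data.set_index("sample_id")
        return idx.loc[list(sample_ids)].reset_index()


@dataclass
class EnvironmentTable:
    """Per-sample gut environment variables (pH, mM concentrations, counts).

    All non-id columns must be numeric; NaN marks a missing measurement.
    pH values, when present, must lie in (0, 14); concentrations must be
    non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns:
            raise ValidationError("environment table missing sample_id column")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in environment table")
        for col in self.variables:
            vals = pd.to_numeric(df[col], errors="coerce")
            df[col] = vals
            if col.lower() == "ph":
                bad = vals.dropna()
                if ((bad <= 0) | (bad >= 14)).any():
                    raise ValidationError("pH outside (0, 14)")
            elif (vals.dropna() < 0).any():
                raise ValidationError(f"negative values in environment column {col!r}")
        self.data = df.reset_index(drop=True)

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c != "sample_id"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])


@dataclass
class AlignedView:
    """Inner join of abundance table, metadata and (optionally) environment."""

    table: AbundanceTable
    meta: SampleMetadata
    env: EnvironmentTable | None
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids


def _normalize_rows(df: pd.DataFrame) -> pd.DataFrame:
    values = df.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = df.index[zero][0]
        raise ValidationError(f"sample {bad!r} has all-zero abundances")
    return pd.DataFrame(values / sums[:, None], index=df.index, columns=df.columns)


def read_abundance_table(
    path: str | Path,
    orientation: str = "samples-in-rows",
    sep: str | None = None,
) -> AbundanceTable:
    """Read a TSV/CSV abundance table and return it normalized to fractions.

    Counts, percentages and fractions are all accepted; each sample row is
    divided by its sum.  ``orientation="taxa-in-rows"`` transposes on read so
    the returned table is always samples-in-rows.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if orientation == "taxa-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.apply(pd.to_numeric, errors="raise")
    if (values.to_numpy() < 0).any():
        arr = values.to_numpy()
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative value at sample {values.index[i]!r}, taxon {values.columns[j]!r}"
        )
    return AbundanceTable(_normalize_rows(values))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a samples-in-rows TSV; first column header is ``sample_id``."""
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_metadata(path: str | Path, sep: str = "\t") -> SampleMetadata:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "subject_id": str})
    return SampleMetadata(df)


def read_environment(path: str | Path, sep: str = "\t") -> EnvironmentTable:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return EnvironmentTable(df)


def filter_prevalent(
    table: AbundanceTable,
    min_mean: float = 0.01,
    sample_ids: Sequence[str] | None = None,
) -> tuple[AbundanceTable, list[str]]:
    """Keep taxa whose mean abundance is strictly above ``min_mean``.

    The mean is taken over ``sample_ids`` when given (the caller decides the
    subset — e.g. infants only), over all samples otherwise, but the returned
    table is restricted to the same subset.  Surviving taxa are *not*
    renormalized: this filter selects variables for networks and heatmaps, it
    does not redefine the composition.

    Returns the filtered (unnormalized) table and the retained taxon list.
    """
    if not 0 <= min_mean < 1:
        raise ValueError(f"min_mean must be in [0, 1), got {min_mean}")
    sub = table if sample_ids is None else table.subset(sample_ids)
    means = sub.data.mean(axis=0)
    keep = [t for t in sub.taxon_ids if means[t] > min_mean]
    return AbundanceTable(sub.data[keep], normalized=False), keep


def align(
    table: AbundanceTable,
    meta: SampleMetadata,
    env: EnvironmentTable | None = None,
) -> AlignedView:
    """Inner-join the three tables on sample id.

    Sample order follows the metadata.  Samples dropped from each input are
    reported in ``dropped``; an empty intersection is an error.
    """
    ids = set(table.sample_ids) & set(meta.sample_ids)
    if env is not None:
        ids &= set(env.sample_ids)
    if not ids:
        raise ValidationError("no samples shared between inputs")
    order = [s for s in meta.sample_ids if s in ids]
    dropped = {
        "table": sorted(set(table.sample_ids) - ids),
        "metadata": sorted(set(meta.sample_ids) - ids),
    }
    aligned_env = None
    if env is not None:
        dropped["environment"] = sorted(set(env.sample_ids) - ids)
        env_df = env.data.set_index("sample_id").loc[order].reset_index()
        aligned_env = EnvironmentTable(env_df)
    sub_meta = SampleMetadata(meta.data[meta.data["sample_id"].isin(ids)])
    return AlignedView(table.subset(order), sub_meta, aligned_env, dropped)
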