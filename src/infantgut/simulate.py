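"""Synthetic cohorts, environment tables, strain panels and growth curves.

The generator mirrors the statistical structure the analysis assumes, so every
pipeline stage can be exercised end to end without external data:

* community composition: per subject, a 3-state Markov chain over composition
  regimes (Staphylococcaceae-, Enterobacteriaceae- and
  Bifidobacteriaceae-dominant) with forward-biased daily transitions; each
  sample's composition is a Dirichlet draw from its regime's concentration
  vector, resampled through a multinomial at finite sequencing depth and
  renormalized — compositional noise of amplicon profiling at ~2,000 reads;
* gut environment: acetate rises linearly with Bifidobacteriaceae abundance,
  pH falls, and residual oligosaccharide falls only when the subject carries
  fucosyllactose-utilizing bifidobacteria (per-subject ``flu`` flag), all with
  additive Gaussian noise truncated at zero (pH clipped to (0, 14));
* strain panels: a planted homologous group equal to the phenotype up to a
  configured number of exception strains, on a background of i.i.d. Bernoulli
  groups, plus logistic growth curves whose carrying capacities sit on the
  correct side of the 0.7 / 0.3 saturating-OD thresholds.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import AbundanceTable, EnvironmentTable, SampleMetadata
from .strains import GrowthCurve

__all__ = [
    "DEFAULT_TAXA",
    "SyntheticCohortConfig",
    "SyntheticPanelConfig",
    "generate_cohort",
    "generate_strain_panel",
    "default_schedule",
    "one_month_survey_config",
]

DEFAULT_TAXA = (
    "Bifidobacteriaceae",
    "Enterobacteriaceae",
    "Staphylococcaceae",
    "Enterococcaceae",
    "Clostridiaceae",
    "Streptococcaceae",
    "Bacteroidaceae",
    "Lactobacillaceae",
)

#: adult-type families used by the one-month survey regime
ADULT_TAXA = (
    "Lachnospiraceae",
    "Ruminococcaceae",
    "Bacteroidaceae",
    "Peptostreptococcaceae",
)


def default_schedule() -> list[int]:
    """Daily sampling in week 1, every other day to one month (17 samples)."""
    return list(range(1, 8)) + list(range(9, 28, 2))


def _default_regimes() -> dict[str, np.ndarray]:
    """Dirichlet concentration vectors, one dominant family per regime.

    Dominant alpha 20 against 7 background alphas of 1 puts the dominant
    family's mean share at 20/27 ≈ 0.74, comfortably "dominant" while leaving
    realistic sample-to-sample scatter.
    """
    base = {t: 1.0 for t in DEFAULT_TAXA}
    regimes = {}
    for label, dominant in (
        ("S", "Staphylococcaceae"),
        ("E", "Enterobacteriaceae"),
        ("B", "Bifidobacteriaceae"),
    ):
        alpha = dict(base)
        alpha[dominant] = 20.0
        regimes[label] = np.array([alpha[t] for t in DEFAULT_TAXA])
    return regimes


def _default_transitions() -> pd.DataFrame:
    """Forward-biased daily transition matrix over S < E < B."""
    forward, backward = 0.15, 0.01
    m = pd.DataFrame(0.0, index=["S", "E", "B"], columns=["S", "E", "B"])
    m.loc["S", "E"] = forward
    m.loc["E", "B"] = forward
    m.loc["E", "S"] = backward
    m.loc["B", "E"] = backward
    for s in m.index:
        m.loc[s, s] = 1.0 - m.loc[s].sum()
    return m


@dataclass
class SyntheticCohortConfig:
    """Study-conditions configuration for the longitudinal cohort generator."""

    n_subjects: int = 12
    days: list[int] = field(default_factory=default_schedule)
    taxa: tuple[str, ...] = DEFAULT_TAXA
    regimes: dict[str, np.ndarray] = field(default_factory=_default_regimes)
    initial_probs: dict[str, float] = field(
        default_factory=lambda: {"S": 0.5, "E": 0.4, "B": 0.1}
    )
    transitions: pd.DataFrame = field(default_factory=_default_transitions)
    depth: int = 2000  # multinomial resampling depth (reads per sample)
    # environment couplings (units: mM for acids/oligosaccharides)
    acetate_intercept: float = 15.0
    acetate_slope: float = 60.0
    acetate_sd: float = 8.0
    ph_intercept: float = 6.8
    ph_slope: float = 1.5
    ph_sd: float = 0.3
    oligo_scale: float = 30.0
    oligo_depletion: float = 0.9  # u: fractional depletion by FL-utilizers
    oligo_sd: float = 4.0
    flu_prob: float = 0.6  # per-subject FL-utilizer colonization probability
    cohort: str = "infant_longitudinal"
    seed: int = 0

    def validate(self) -> None:
        t = self.transitions
        if list(t.index) != list(t.columns):
            raise ValueError("transition matrix index/columns mismatch")
        if set(t.index) != set(self.regimes):
            raise ValueError("transition states must match regime labels")
        if ((t < 0).to_numpy()).any() or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must be probabilities summing to 1")
        if min(self.acetate_slope, self.ph_slope, self.oligo_depletion) < 0:
            raise ValueError("coupling strengths must be non-negative")
        for label, alpha in self.regimes.items():
            if len(alpha) != len(self.taxa) or np.any(np.asarray(alpha) <= 0):
                raise ValueError(f"invalid Dirichlet concentration for regime {label}")


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[AbundanceTable, SampleMetadata, EnvironmentTable, pd.DataFrame]:
    """Simulate a longitudinal cohort.

    Returns the abundance table, metadata, environment table and a ground
    truth frame (sample_id, subject_id, day, regime, flu) for recovery tests.
    """
    config = config or SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    states = list(config.transitions.index)
    tmat = config.transitions.to_numpy()
    init = np.array([config.initial_probs[s] for s in states])
    init = init / init.sum()
    bifido_idx = (
        config.taxa.index("Bifidobacteriaceae")
        if "Bifidobacteriaceae" in config.taxa
        else None
    )

    rows, meta_rows, env_rows, truth_rows = [], [], [], []
    sample_ids = []
    for si in range(config.n_subjects):
        subject = f"S{si + 1:02d}"
        flu = int(rng.random() < config.flu_prob)
        state = int(rng.choice(len(states), p=init))
        prev_day = config.days[0]
        for day in config.days:
            for _ in range(day - prev_day):  # advance the daily chain
                state = int(rng.choice(len(states), p=tmat[state]))
            prev_day = day
            regime = states[state]
            p = rng.dirichlet(config.regimes[regime])
            counts = rng.multinomial(config.depth, p)
            comp = counts / counts.sum()
            sample = f"{subject}D{day:02d}"
            sample_ids.append(sample)
            rows.append(comp)
            meta_rows.append(
                {
                    "sample_id": sample,
                    "subject_id": subject,
                    "day": day,
                    "cohort": config.cohort,
                    "flu": flu,
                }
            )
            bif = comp[bifido_idx] if bifido_idx is not None else 0.0
            acetate = config.acetate_intercept + config.acetate_slope * bif
            acetate += rng.normal(0, config.acetate_sd)
            ph = config.ph_intercept - config.ph_slope * bif + rng.normal(0, config.ph_sd)
            oligo = config.oligo_scale * (1.0 - config.oligo_depletion * flu * bif)
            oligo += rng.normal(0, config.oligo_sd)
            env_rows.append(
                {
                    "sample_id": sample,
                    "pH": float(np.clip(ph, 1e-6, 14 - 1e-6)),
                    "acetate": max(acetate, 0.0),
                    "oligosaccharide": max(oligo, 0.0),
                }
            )
            truth_rows.append(
                {
                    "sample_id": sample,
                    "subject_id": subject,
                    "day": day,
                    "regime": regime,
                    "flu": flu,
                }
            )
    table = AbundanceTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=list(config.taxa))
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    env = EnvironmentTable(pd.DataFrame(env_rows))
    truth = pd.DataFrame(truth_rows)
    return table, meta, env, truth


def one_month_survey_config(
    n_cluster_b: int = 18,
    n_cluster_e: int = 9,
    n_adults: int = 22,
    seed: int = 0,
) -> SyntheticCohortConfig:
    """Cross-sectional survey config: one sample each from one-month infants
    (Bifidobacteriaceae- or Enterobacteriaceae-dominant) and adults.

    Implemented as a degenerate longitudinal config (single day, identity
    transitions) whose initial state is forced per subject by
    :func:`generate_survey`; provided so the survey reuses the cohort
    machinery and taxa.
    """
    taxa = tuple(dict.fromkeys(DEFAULT_TAXA + ADULT_TAXA))
    base = {t: 0.5 for t in taxa}
    regimes = {}
    for label, dominants in (
        ("B", ("Bifidobacteriaceae",)),
        ("E", ("Enterobacteriaceae",)),
        ("AD", ADULT_TAXA),
    ):
        alpha = dict(base)
        for d in dominants:
            alpha[d] = 20.0 / len(dominants) + 2.0
        regimes[label] = np.array([alpha[t] for t in taxa])
    identity = pd.DataFrame(np.eye(3), index=["B", "E", "AD"], columns=["B", "E", "AD"])
    cfg = SyntheticCohortConfig(
        n_subjects=n_cluster_b + n_cluster_e + n_adults,
        days=[29],
        taxa=taxa,
        regimes=regimes,
        initial_probs={"B": 0.0, "E": 0.0, "AD": 1.0},
        transitions=identity,
        seed=seed,
    )
    cfg._survey_sizes = (n_cluster_b, n_cluster_e, n_adults)  # type: ignore[attr-defined]
    return cfg


def generate_survey(
    config: SyntheticCohortConfig,
) -> tuple[AbundanceTable, SampleMetadata, EnvironmentTable, pd.DataFrame]:
    """Cross-sectional one-month survey with fixed per-group sample counts."""
    n_b, n_e, n_ad = getattr(config, "_survey_sizes")
    config.validate()
    rng = np.random.default_rng(config.seed)
    assignments = ["B"] * n_b + ["E"] * n_e + ["AD"] * n_ad
    rows, meta_rows, env_rows, truth_rows, sample_ids = [], [], [], [], []
    bifido_idx = config.taxa.index("Bifidobacteriaceae")
    for i, regime in enumerate(assignments):
        adult = regime == "AD"
        subject = f"{'P' if adult else 'I'}{i + 1:02d}"
        sample = f"{subject}M1"
        p = rng.dirichlet(config.regimes[regime])
        counts = rng.multinomial(config.depth, p)
        comp = counts / counts.sum()
        flu = int(regime == "B" and rng.random() < config.flu_prob)
        sample_ids.append(sample)
        rows.append(comp)
        meta_rows.append(
            {
                "sample_id": sample,
                "subject_id": subject,
                "day": None if adult else 29,
                "cohort": "adult" if adult else "infant_1mo",
                "flu": flu,
            }
        )
        bif = comp[bifido_idx]
        env_rows.append(
            {
                "sample_id": sample,
                "pH": float(
                    np.clip(
                        config.ph_intercept - config.ph_slope * bif
                        + rng.normal(0, config.ph_sd),
                        1e-6,
                        14 - 1e-6,
                    )
                ),
                "acetate": max(
                    config.acetate_intercept + config.acetate_slope * bif
                    + rng.normal(0, config.acetate_sd),
                    0.0,
                ),
                "oligosaccharide": max(
                    config.oligo_scale * (1 - config.oligo_depletion * flu * bif)
                    + rng.normal(0, config.oligo_sd),
                    0.0,
                ),
            }
        )
        truth_rows.append(
            {"sample_id": sample, "subject_id": subject, "regime": regime, "flu": flu}
        )
    table = AbundanceTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=list(config.taxa))
    )
    return (
        table,
        SampleMetadata(pd.DataFrame(meta_rows)),
        EnvironmentTable(pd.DataFrame(env_rows)),
        pd.DataFrame(truth_rows),
    )


@dataclass
class SyntheticPanelConfig:
    """Configuration for the synthetic strain panel generator."""

    n_strains: int = 29
    n_groups: int = 2000
    background_prob: float = 0.5
    n_growers: int = 14
    planted_group: str = "HG_planted"
    n_exceptions: int = 1
    exception_direction: str = "absent_but_grower"
    grower_capacity: tuple[float, float] = (0.9, 1.1)  # uniform range, > 0.7
    non_grower_capacity: tuple[float, float] = (0.05, 0.2)  # < 0.3
    growth_rate: float = 0.4  # logistic rate per hour
    midpoint_h: float = 12.0
    od_noise_sd: float = 0.01
    times_h: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 40.5, 2.0)
    )
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_exceptions >= self.n_strains / 2:
            raise ValueError("n_exceptions must be below half the panel")
        if not 0 < self.n_growers < self.n_strains:
            raise ValueError("n_growers must split the panel")
        if self.grower_capacity[0] <= 0.7:
            raise ValueError("grower capacities must exceed the 0.7 threshold")
        if self.non_grower_capacity[1] >= 0.3:
            raise ValueError("non-grower capacities must stay below the 0.3 threshold")
        if self.exception_direction not in (
            "absent_but_grower",
            "present_but_non_grower",
        ):
            raise ValueError(f"unknown direction {self.exception_direction!r}")


def generate_strain_panel(
    config: SyntheticPanelConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[GrowthCurve]]]:
    """Simulate a strain panel with one planted discriminating group.

    Returns (presence matrix, phenotype series, growth curves per strain).
    The planted column equals the phenotype with ``n_exceptions`` strains
    flipped in the configured direction; all other groups are i.i.d.
    Bernoulli(``background_prob``).  Growth curves are logistic with
    class-dependent carrying capacity plus truncated Gaussian noise, so
    noiseless classification reproduces the generating phenotype.
    """
    config = config or SyntheticPanelConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    strains = [f"ST{i + 1:02d}" for i in range(config.n_strains)]
    grower_mask = np.zeros(config.n_strains, dtype=bool)
    grower_mask[
        rng.choice(config.n_strains, size=config.n_growers, replace=False)
    ] = True
    phenotype = pd.Series(
        np.where(grower_mask, "grower", "non_grower"), index=strains, name="hmo_growth"
    )

    planted = grower_mask.astype(int).copy()
    if config.exception_direction == "absent_but_grower":
        pool = np.flatnonzero(grower_mask)
        flip_to = 0
    else:
        pool = np.flatnonzero(~grower_mask)
        flip_to = 1
    if config.n_exceptions > pool.size:
        raise ValueError("planted exceptions exceed phenotype class size")
    flips = rng.choice(pool, size=config.n_exceptions, replace=False)
    planted[flips] = flip_to

    background = rng.random((config.n_strains, config.n_groups - 1))
    background = (background < config.background_prob).astype(int)
    group_ids = [f"HG_{i + 1:04d}" for i in range(config.n_groups - 1)]
    mat = pd.DataFrame(background, index=strains, columns=group_ids)
    # insert the planted group at a reproducible position
    pos = int(rng.integers(0, config.n_groups))
    mat.insert(pos, config.planted_group, planted)
    mat.index.name = "strain_id"

    curves: dict[str, list[GrowthCurve]] = {}
    t = np.asarray(config.times_h, dtype=float)
    for i, strain in enumerate(strains):
        lo, hi = (
            config.grower_capacity if grower_mask[i] else config.non_grower_capacity
        )
        cap = rng.uniform(lo, hi)
        reps = []
        for r in range(config.n_replicates):
            od = cap / (1.0 + np.exp(-config.growth_rate * (t - config.midpoint_h)))
            od = np.maximum(od + rng.normal(0, config.od_noise_sd, size=t.size), 0.0)
            reps.append(GrowthCurve(strain, t, od, replicate=r + 1))
        curves[strain] = reps
    return mat, phenotype, curves
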