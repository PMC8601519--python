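"""Synthetic cohorts with known ground truth.

Two generators mirror the two natural entry points of the pipeline:

* ``factor_timeseries`` produces regional activity matrices from a latent
  single-factor model: region i's series is ``lambda_i * g(t) + noise``,
  so the expected sign of the Pearson correlation between two regions is
  the product of their loading signs.  The stage knob controls the fraction
  of negative loadings and hence the negative-link density of the derived
  signed network.
* ``direct_network`` produces fully connected signed networks directly,
  drawing each subject's negative-link probability from a Beta distribution
  centred on the stage's target density, so median frustration differs
  across stages by construction.

Defaults emulate the study design: five lifespan stages with the real
cohort's per-stage sizes and female fractions, 268 regions, and a u-shaped
negative-density profile with its minimum in early adulthood.  The
generators make no attempt at BOLD-like autocorrelation or scanner noise;
they exist so every downstream stage is testable without neuroimaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .census import census_trace
from .network import RegionalTimeSeries, SignedNetwork
from .stats import STAGES

__all__ = [
    "STAGES",
    "DEFAULT_SUBJECTS_PER_STAGE",
    "DEFAULT_NEG_DENSITY_BY_STAGE",
    "DEFAULT_FEMALE_FRACTION_BY_STAGE",
    "SyntheticCohortSpec",
    "GroundTruth",
    "CohortSubject",
    "generate_factor_timeseries",
    "generate_balanced_network",
    "flip_edges",
    "generate_staged_cohort",
]

# Stage sizes and female counts of the pooled ABIDE + Southwest cohort.
DEFAULT_SUBJECTS_PER_STAGE: dict[str, int] = {
    "child": 121,
    "adolescent": 148,
    "early_adult": 265,
    "middle_adult": 211,
    "late_adult": 48,
}

DEFAULT_FEMALE_FRACTION_BY_STAGE: dict[str, float] = {
    "child": 32 / 121,
    "adolescent": 32 / 148,
    "early_adult": 117 / 265,
    "middle_adult": 140 / 211,
    "late_adult": 29 / 48,
}

# U-shaped negative-link density over the lifespan, minimum in early
# adulthood; negative links are a minority of a resting-state network.
DEFAULT_NEG_DENSITY_BY_STAGE: dict[str, float] = {
    "child": 0.14,
    "adolescent": 0.12,
    "early_adult": 0.10,
    "middle_adult": 0.12,
    "late_adult": 0.14,
}

_AGE_RANGE: dict[str, tuple[float, float]] = {
    "child": (6, 12),
    "adolescent": (12, 18),
    "early_adult": (18, 40),
    "middle_adult": (40, 65),
    "late_adult": (65, 80),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full parameterization of a synthetic cohort.

    ``neg_density_by_stage`` is the target negative-link density per stage in
    ``direct_network`` mode, and the fraction of negative factor loadings in
    ``factor_timeseries`` mode.  ``density_dispersion`` is the Beta
    concentration (kappa) of the per-subject density draw; larger means less
    between-subject spread.  ``sex_effect`` additively shifts the male
    density target (0 = sex carries no signal).
    """

    n_subjects_per_stage: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBJECTS_PER_STAGE)
    )
    n_regions: int = 268
    n_timepoints: int = 150
    generator_kind: str = "direct_network"
    neg_density_by_stage: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEG_DENSITY_BY_STAGE)
    )
    density_dispersion: float = 400.0
    noise_sd: float = 1.0
    n_factors: int = 1
    sex_effect: float = 0.0
    female_fraction_by_stage: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_FRACTION_BY_STAGE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator_kind not in ("factor_timeseries", "direct_network"):
            raise ValueError(f"unknown generator kind {self.generator_kind!r}")
        if not self.n_subjects_per_stage:
            raise ValueError("at least one stage must be populated")
        for stage, n in self.n_subjects_per_stage.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if n < 1:
                raise ValueError(f"stage {stage!r} must have >= 1 subject")
        for stage in self.n_subjects_per_stage:
            f = self.neg_density_by_stage.get(stage)
            if f is None or not (0 <= f <= 1):
                raise ValueError(f"stage {stage!r} needs a density fraction in [0, 1]")
        if self.n_regions < 1 or self.n_timepoints < 1:
            raise ValueError("dimensions must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.density_dispersion <= 0:
            raise ValueError("density_dispersion must be positive")

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(s for s in STAGES if s in self.n_subjects_per_stage)


@dataclass(frozen=True)
class GroundTruth:
    """Per-subject construction truth attached to every generated subject."""

    subject_id: str
    stage: str
    sex: str
    age: float
    true_neg_density: float
    constructed_frustration: int | None = None


@dataclass(frozen=True)
class CohortSubject:
    """A generated subject: metadata plus its signed network."""

    subject_id: str
    stage: str
    sex: str
    age: float
    network: SignedNetwork
    truth: GroundTruth


def _subject_streams(spec: SyntheticCohortSpec) -> list[tuple[str, str, np.random.Generator]]:
    """Deterministic (stage, subject_id, rng) triples in fixed stage order."""
    ss = np.random.SeedSequence(spec.seed)
    out = []
    children = iter(ss.spawn(sum(spec.n_subjects_per_stage[s] for s in spec.stages)))
    for stage in spec.stages:
        for i in range(spec.n_subjects_per_stage[stage]):
            out.append((stage, f"{stage}_{i:04d}", np.random.default_rng(next(children))))
    return out


def _draw_demographics(
    spec: SyntheticCohortSpec, stage: str, rng: np.random.Generator
) -> tuple[str, float]:
    sex = "female" if rng.random() < spec.female_fraction_by_stage.get(stage, 0.5) else "male"
    lo, hi = _AGE_RANGE[stage]
    age = float(rng.uniform(lo, hi))
    return sex, age


def generate_factor_timeseries(
    spec: SyntheticCohortSpec,
) -> list[tuple[RegionalTimeSeries, GroundTruth]]:
    """Generate latent-factor regional time series for every subject."""
    if spec.generator_kind != "factor_timeseries":
        raise ValueError("spec.generator_kind must be 'factor_timeseries'")
    labels = tuple(f"R{i:03d}" for i in range(spec.n_regions))
    out = []
    for stage, sid, rng in _subject_streams(spec):
        sex, age = _draw_demographics(spec, stage, rng)
        frac_neg = float(spec.neg_density_by_stage[stage])
        signs = np.where(rng.random(spec.n_regions) < frac_neg, -1.0, 1.0)
        # loading magnitudes bounded away from 0 so the factor dominates
        # pairwise correlations as noise_sd -> 0
        loadings = signs[:, None] * rng.uniform(
            0.8, 1.2, size=(spec.n_regions, spec.n_factors)
        )
        factors = rng.standard_normal((spec.n_factors, spec.n_timepoints))
        values = loadings @ factors + spec.noise_sd * rng.standard_normal(
            (spec.n_regions, spec.n_timepoints)
        )
        opposite = np.not_equal.outer(signs < 0, signs < 0)
        iu = np.triu_indices(spec.n_regions, k=1)
        truth = GroundTruth(
            subject_id=sid,
            stage=stage,
            sex=sex,
            age=age,
            true_neg_density=float(opposite[iu].mean()),
        )
        out.append((RegionalTimeSeries(values, labels, sid), truth))
    return out


def generate_balanced_network(
    n_regions: int, faction_sizes: tuple[int, int]
) -> SignedNetwork:
    """Complete two-faction signed network: +1 within factions, -1 between.

    By the structure theorem of strong balance every closed triad of such a
    network is balanced, so its frustration count is zero.
    """
    n1, n2 = faction_sizes
    if n1 < 0 or n2 < 0 or n1 + n2 != n_regions:
        raise ValueError(f"faction sizes {faction_sizes} inconsistent with n={n_regions}")
    membership = np.ones(n_regions, dtype=np.int8)
    membership[n1:] = -1
    adjacency = np.outer(membership, membership).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return SignedNetwork(adjacency, provenance={"generator": "balanced_two_faction"})


def flip_edges(
    net: SignedNetwork, k: int, seed: int
) -> tuple[SignedNetwork, list[tuple[int, int]]]:
    """Negate the sign of ``k`` distinct present edges chosen at random.

    The presence pattern is unchanged, so this injects frustration without
    altering topology; flipping the same edge twice restores the original.
    """
    iu = np.triu_indices(net.n_nodes, k=1)
    present = np.flatnonzero(net.adjacency[iu] != 0)
    if k < 0 or k > present.size:
        raise ValueError(f"k={k} outside [0, {present.size}] present edges")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(present, size=k, replace=False)
    adjacency = net.adjacency.copy()
    pairs = []
    for idx in chosen:
        i, j = int(iu[0][idx]), int(iu[1][idx])
        adjacency[i, j] = -adjacency[i, j]
        adjacency[j, i] = -adjacency[j, i]
        pairs.append((i, j))
    return SignedNetwork(adjacency, net.region_labels, net.provenance), pairs


def _draw_density(
    mean: float, dispersion: float, rng: np.random.Generator
) -> float:
    if mean <= 0.0 or mean >= 1.0:
        return float(mean)
    return float(rng.beta(mean * dispersion, (1 - mean) * dispersion))


def generate_staged_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[CohortSubject], list[GroundTruth]]:
    """Generate fully connected signed networks for a staged cohort."""
    if spec.generator_kind != "direct_network":
        raise ValueError("spec.generator_kind must be 'direct_network'")
    labels = tuple(f"R{i:03d}" for i in range(spec.n_regions))
    iu = np.triu_indices(spec.n_regions, k=1)
    subjects: list[CohortSubject] = []
    truths: list[GroundTruth] = []
    for stage, sid, rng in _subject_streams(spec):
        sex, age = _draw_demographics(spec, stage, rng)
        target = float(spec.neg_density_by_stage[stage])
        if sex == "male" and spec.sex_effect:
            target = float(np.clip(target + spec.sex_effect, 0.0, 1.0))
        p_neg = _draw_density(target, spec.density_dispersion, rng)
        signs = np.where(rng.random(iu[0].size) < p_neg, -1, 1).astype(np.int8)
        adjacency = np.zeros((spec.n_regions, spec.n_regions), dtype=np.int8)
        adjacency[iu] = signs
        adjacency += adjacency.T
        net = SignedNetwork(
            adjacency, labels, provenance={"subject_id": sid, "generator": "direct_network"}
        )
        truth = GroundTruth(
            subject_id=sid,
            stage=stage,
            sex=sex,
            age=age,
            true_neg_density=p_neg,
            constructed_frustration=census_trace(net).n_frustrated,
        )
        subjects.append(CohortSubject(sid, stage, sex, age, net, truth))
        truths.append(truth)
    return subjects, truths
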