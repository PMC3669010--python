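"""Generative simulator for censored qPCR triplicate datasets.

The data-generating process mirrors a community-DNA qPCR workflow: each
sample's true log10 gene quantity per gram is drawn from a normal
regression on a binary risk factor; DNA extraction recovers a fixed
fraction ``q`` of the copies into one extract volume; replicate reaction
aliquots are drawn from the extract by a Dirichlet-multinomial (the
Dirichlet layer supplies the extra-binomial variation seen in real
triplicates); and replicate counts below the limit of quantification
(LOQ) are left-censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ScenarioConfig",
    "SampleRecord",
    "CensoredDataset",
    "simulate_true_quantities",
    "copies_in_extract",
    "draw_aliquots",
    "censor_replicate",
    "simulate_dataset",
    "censoring_summary",
]

CENSORED = None  # marker: censored replicates carry no numeric value


class ConfigError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


class DataError(ValueError):
    """Raised for out-of-contract data values (e.g. negative counts)."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative and assay parameters for one simulation scenario.

    Parameters
    ----------
    beta0, beta1 : float
        Regression intercept and binary-covariate effect, in log10 gene
        copies per gram of sample.
    sigma : float
        Standard deviation of the per-sample log10 quantity.
    n_samples : int
        Samples per simulated dataset.
    risk_fraction : float
        Probability that a sample carries the binary risk factor.
    n_replicates : int
        Technical replicates (reaction aliquots) per sample.
    extract_volume_ul, aliquot_volume_ul : float
        DNA extract volume and the volume pipetted into each reaction.
        Their ratio (default 5/1000 = 0.005) is the expected proportion
        of extract copies entering one reaction.
    extraction_efficiency : float
        Fraction ``q`` of a sample's gene copies recovered by DNA
        extraction (default 0.65).
    loq : int
        Limit of quantification in copies per reaction; replicate counts
        below it are censored.
    dirichlet_concentration : float
        Total concentration of the Dirichlet distribution over aliquot
        proportions.  Finite values give counts that are overdispersed
        relative to a fixed-probability multinomial; the multinomial is
        recovered as the concentration grows.
    seed : int, optional
        Seed for dataset generation when no generator is passed in.
    """

    beta0: float
    beta1: float
    sigma: float
    n_samples: int = 500
    risk_fraction: float = 0.5
    n_replicates: int = 3
    extract_volume_ul: float = 1000.0
    aliquot_volume_ul: float = 5.0
    extraction_efficiency: float = 0.65
    loq: int = 10
    dirichlet_concentration: float = 1000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if not 0 < self.extraction_efficiency <= 1:
            raise ConfigError(
                f"extraction_efficiency must be in (0, 1], got "
                f"{self.extraction_efficiency}"
            )
        if not 0 <= self.risk_fraction <= 1:
            raise ConfigError(
                f"risk_fraction must be in [0, 1], got {self.risk_fraction}"
            )
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not (
            self.n_replicates * self.aliquot_volume_ul < self.extract_volume_ul
        ):
            raise ConfigError(
                "total aliquot volume must be smaller than the extract volume"
            )
        if self.loq < 0 or int(self.loq) != self.loq:
            raise ConfigError(f"loq must be a nonnegative integer, got {self.loq}")
        if not self.dirichlet_concentration > 0:
            raise ConfigError("dirichlet_concentration must be > 0")

    @property
    def aliquot_fraction(self) -> float:
        """Expected proportion of extract copies in one reaction (p)."""
        return self.aliquot_volume_ul / self.extract_volume_ul

    @property
    def aliquot_probabilities(self) -> np.ndarray:
        """Mean Dirichlet probabilities for the replicates + remainder."""
        p = self.aliquot_fraction
        probs = np.full(self.n_replicates + 1, p)
        probs[-1] = 1.0 - self.n_replicates * p
        return probs

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SampleRecord:
    """One sample: covariate, optional truth, and replicate observations.

    ``replicate_counts`` holds the observed copy number for uncensored
    replicates and ``None`` for censored ones; ``censored_flags`` marks
    the censored positions.  Censored replicates never carry a numeric
    value, which rules out accidental use as data.
    """

    sample_id: str
    risk_indicator: int
    replicate_counts: tuple[int | None, ...]
    censored_flags: tuple[bool, ...]
    true_log10_quantity: float | None = None
    mass_g: float = 1.0

    def __post_init__(self) -> None:
        if len(self.replicate_counts) != len(self.censored_flags):
            raise DataError(
                f"sample {self.sample_id}: replicate_counts and "
                "censored_flags differ in length"
            )
        for value, flagged in zip(self.replicate_counts, self.censored_flags):
            if flagged and value is not None:
                raise DataError(
                    f"sample {self.sample_id}: censored replicate carries a value"
                )
            if not flagged and (value is None or value < 0):
                raise DataError(
                    f"sample {self.sample_id}: uncensored replicate must be a "
                    "nonnegative count"
                )

    @property
    def n_censored(self) -> int:
        return sum(self.censored_flags)


@dataclass
class CensoredDataset:
    """A collection of samples sharing one assay configuration."""

    records: list[SampleRecord]
    config: ScenarioConfig

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("a dataset must contain at least one record")
        loq = self.config.loq
        for rec in self.records:
            for value, flagged in zip(rec.replicate_counts, rec.censored_flags):
                if not flagged and value < loq:
                    raise DataError(
                        f"sample {rec.sample_id}: uncensored count {value} is "
                        f"below the LOQ ({loq})"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.records)

    @property
    def n_observations(self) -> int:
        return sum(len(r.replicate_counts) for r in self.records)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (counts, censored, risk) arrays.

        ``counts`` is float with NaN at censored positions; ``censored``
        is boolean; ``risk`` is the 0/1 covariate vector.
        """
        n = self.n_samples
        r = self.config.n_replicates
        counts = np.full((n, r), np.nan)
        censored = np.zeros((n, r), dtype=bool)
        risk = np.zeros(n, dtype=int)
        for j, rec in enumerate(self.records):
            risk[j] = rec.risk_indicator
            for i, (value, flagged) in enumerate(
                zip(rec.replicate_counts, rec.censored_flags)
            ):
                censored[j, i] = flagged
                if not flagged:
                    counts[j, i] = value
        return counts, censored, risk

    def true_quantities(self) -> np.ndarray | None:
        vals = [r.true_log10_quantity for r in self.records]
        if any(v is None for v in vals):
            return None
        return np.asarray(vals, dtype=float)


def simulate_true_quantities(
    config: ScenarioConfig, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Draw (risk_indicator, true log10 quantity per gram) pairs.

    Risk indicators are Bernoulli(``risk_fraction``); the log10 quantity
    is normal with mean ``beta0 + beta1 * risk`` and sd ``sigma``.
    """
    risk = rng.random(config.n_samples) < config.risk_fraction
    y = rng.normal(
        config.beta0 + config.beta1 * risk, config.sigma, size=config.n_samples
    )
    return [(int(r), float(v)) for r, v in zip(risk, y)]


def copies_in_extract(y: float, q: float) -> int:
    """Gene copies recovered into the DNA extract.

    ``round(q * 10**y)``, half away from zero; the count feeds a
    multinomial and must be a nonnegative integer.
    """
    if not 0 < q <= 1:
        raise ConfigError(f"extraction efficiency must be in (0, 1], got {q}")
    copies = q * 10.0**y
    return int(math.floor(copies + 0.5))


def draw_aliquots(
    n_copies: int, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Partition extract copies into replicate aliquots plus remainder.

    Draws probabilities from Dirichlet(concentration * mean_probs) and
    counts from Multinomial(n_copies, p); the final entry is the unused
    remainder.  Counts always sum to ``n_copies``.
    """
    if n_copies < 0:
        raise DataError(f"n_copies must be >= 0, got {n_copies}")
    alpha = config.dirichlet_concentration * config.aliquot_probabilities
    p = rng.dirichlet(alpha)
    return rng.multinomial(n_copies, p)


def censor_replicate(x: int, loq: int) -> int | None:
    """Apply the LOQ censoring rule to one replicate count.

    Counts at or above the LOQ are observed unchanged; counts below it
    are censored and the numeric value is discarded.
    """
    if x < 0:
        raise DataError(f"replicate count must be >= 0, got {x}")
    return int(x) if x >= loq else CENSORED


def simulate_dataset(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> CensoredDataset:
    """Simulate one censored dataset under the scenario configuration."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    truths = simulate_true_quantities(config, rng)
    for j, (risk, y) in enumerate(truths):
        n_copies = copies_in_extract(y, config.extraction_efficiency)
        aliquots = draw_aliquots(n_copies, config, rng)
        observed = [
            censor_replicate(int(x), config.loq)
            for x in aliquots[: config.n_replicates]
        ]
        records.append(
            SampleRecord(
                sample_id=f"s{j + 1}",
                risk_indicator=risk,
                replicate_counts=tuple(observed),
                censored_flags=tuple(v is None for v in observed),
                true_log10_quantity=y,
            )
        )
    return CensoredDataset(records=records, config=config)


def censoring_summary(
    dataset: CensoredDataset,
) -> tuple[float, tuple[int, ...]]:
    """Fraction of censored replicates and sample counts by censoring level.

    Returns ``(fraction_censored, counts)`` where ``counts[k]`` is the
    number of samples with exactly ``k`` censored replicates,
    ``k = 0 .. n_replicates``.
    """
    r = dataset.config.n_replicates
    by_level = [0] * (r + 1)
    n_censored = 0
    n_total = 0
    for rec in dataset.records:
        k = rec.n_censored
        by_level[k] += 1
        n_censored += k
        n_total += len(rec.censored_flags)
    return n_censored / n_total, tuple(by_level)
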