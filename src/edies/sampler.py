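"""Severity-reweighted resampling and CI-coverage experiments for Ws.

A sampling scenario either draws simple random samples ("random" mode) or
reshapes the severity mix to a discretized gamma density ("gamma" mode):
the target fraction of each severity stratum is the gamma mass integrated
over the unit intervals [s, s+1) of its member scores.  Repeated samples
from a fixed population measure how often the 95% CI of the sample Ws
covers the population Ws.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .scoring import ReferenceTable
from .wstats import WsError, ws_statistic


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class SamplingScenario:
    """Specification of one resampling experiment."""

    mode: str  # "random" or "gamma"
    sample_size: int = 30_000
    replicates: int = 1000
    seed: int = 0
    shape: Optional[float] = None
    rate: Optional[float] = None
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("random", "gamma"):
            raise ScenarioError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "gamma":
            if self.shape is None or self.rate is None or self.shape <= 0 or self.rate <= 0:
                raise ScenarioError("gamma mode requires positive shape and rate")
        if self.sample_size <= 0 or self.replicates <= 0:
            raise ScenarioError("sample_size and replicates must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "SamplingScenario":
        return cls(**{k: data[k] for k in
                      ("mode", "sample_size", "replicates", "seed", "shape", "rate",
                       "with_replacement") if k in data})

    def to_dict(self) -> dict:
        return {"mode": self.mode, "sample_size": self.sample_size,
                "replicates": self.replicates, "seed": self.seed,
                "shape": self.shape, "rate": self.rate,
                "with_replacement": self.with_replacement}


@dataclass(frozen=True)
class CoverageResult:
    """Outcome of a coverage experiment."""

    population_ws: float
    replicate_ws: tuple[float, ...]
    coverage_pct: float
    mean_replicate_ws: float

    def to_dict(self, include_replicates: bool = True) -> dict:
        out = {
            "population_ws": self.population_ws,
            "coverage_pct": self.coverage_pct,
            "mean_replicate_ws": self.mean_replicate_ws,
            "n_replicates": len(self.replicate_ws),
        }
        if include_replicates:
            out["replicate_ws"] = list(self.replicate_ws)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def gamma_target_distribution(
    shape: float,
    rate: float,
    strata: Sequence[Sequence[int]],
) -> np.ndarray:
    """Target stratum fractions under a gamma(shape, rate) severity model.

    Each stratum's raw weight is the gamma density mass over the union of
    unit intervals [s, s+1) of its member scores; weights are renormalized
    to sum to 1 over the given strata.
    """
    if shape <= 0 or rate <= 0:
        raise ScenarioError("shape and rate must be positive")
    if not len(strata):
        raise ScenarioError("strata must be non-empty")
    dist = gamma_dist(a=shape, scale=1.0 / rate)
    weights = np.array([
        sum(dist.cdf(s + 1) - dist.cdf(s) for s in group) for group in strata
    ])
    total = weights.sum()
    if total <= 0:
        raise ScenarioError("gamma density places no mass on the given strata")
    return weights / total


def largest_remainder(weights: Sequence[float], n: int) -> np.ndarray:
    """Apportion ``n`` into integer counts proportional to ``weights``
    (Hamilton / largest-remainder method; ties broken by position)."""
    weights = np.asarray(weights, dtype=float)
    if n < 0 or weights.min() < 0 or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum; n >= 0")
    quotas = n * weights / weights.sum()
    counts = np.floor(quotas).astype(np.int64)
    shortfall = n - int(counts.sum())
    if shortfall:
        remainders = quotas - counts
        # stable sort => earlier strata win exact remainder ties
        for idx in np.argsort(-remainders, kind="stable")[:shortfall]:
            counts[idx] += 1
    return counts


def stratified_resample(
    scores: np.ndarray,
    died: np.ndarray,
    strata: Sequence[Sequence[int]],
    target: Sequence[float],
    n: int,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a sample of exactly ``n`` whose stratum counts follow
    ``target`` via largest-remainder apportionment.

    Within each stratum, members are drawn uniformly without replacement;
    if a stratum holds fewer members than its quota the draw falls back to
    with-replacement with a warning.
    """
    scores = np.asarray(scores)
    died = np.asarray(died)
    counts = largest_remainder(target, n)
    member_idx = [np.flatnonzero(np.isin(scores, np.asarray(group))) for group in strata]
    picks = []
    for group, quota, members in zip(strata, counts, member_idx):
        if quota == 0:
            continue
        if members.size == 0:
            raise ScenarioError(
                f"target places mass on stratum {tuple(group)} absent from the population"
            )
        replace = with_replacement
        if not replace and members.size < quota:
            warnings.warn(
                f"stratum {tuple(group)}: quota {quota} exceeds population size "
                f"{members.size}; sampling with replacement", UserWarning, stacklevel=2)
            replace = True
        picks.append(rng.choice(members, size=int(quota), replace=replace))
    chosen = np.concatenate(picks)
    return scores[chosen], died[chosen]


def simple_random_sample(
    scores: np.ndarray,
    died: np.ndarray,
    n: int,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.choice(scores.size, size=n, replace=with_replacement)
    return scores[idx], died[idx]


def draw_sample(
    scores: np.ndarray,
    died: np.ndarray,
    reference: ReferenceTable,
    scenario: SamplingScenario,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One sample according to the scenario (simple random or
    gamma-reweighted stratified)."""
    if scenario.mode == "random":
        return simple_random_sample(scores, died, scenario.sample_size, rng,
                                    scenario.with_replacement)
    strata = [s.scores for s in reference.strata]
    target = gamma_target_distribution(scenario.shape, scenario.rate, strata)
    return stratified_resample(scores, died, strata, target, scenario.sample_size,
                               rng, scenario.with_replacement)


def coverage_experiment(
    scores: np.ndarray,
    died: np.ndarray,
    reference: ReferenceTable,
    scenario: SamplingScenario,
) -> CoverageResult:
    """Measure 95% CI coverage of the population Ws under repeated sampling.

    The population Ws is computed once from the full population; each of
    ``scenario.replicates`` samples gets its own independent substream of
    the scenario seed, and coverage is the percentage of replicate CIs that
    contain the population Ws.
    """
    scores = np.asarray(scores, dtype=np.int64)
    died = np.asarray(died, dtype=bool)
    population = ws_statistic(scores, reference, outcomes=died)
    target_ws = population.ws

    if scenario.mode == "gamma":
        # precompute stratum membership and quotas once; replicates reuse them
        strata = [s.scores for s in reference.strata]
        target = gamma_target_distribution(scenario.shape, scenario.rate, strata)
        member_idx = [np.flatnonzero(np.isin(scores, np.asarray(g))) for g in strata]
        counts = largest_remainder(target, scenario.sample_size)
        for group, quota, members in zip(strata, counts, member_idx):
            if quota > 0 and members.size == 0:
                raise ScenarioError(
                    f"target places mass on stratum {tuple(group)} absent from the population"
                )
            if not scenario.with_replacement and 0 < members.size < quota:
                warnings.warn(
                    f"stratum {tuple(group)}: quota {quota} exceeds population size "
                    f"{members.size}; sampling with replacement", UserWarning, stacklevel=2)

        def draw(rng: np.random.Generator):
            picks = [
                rng.choice(members, size=int(quota),
                           replace=scenario.with_replacement or members.size < quota)
                for quota, members in zip(counts, member_idx) if quota > 0
            ]
            chosen = np.concatenate(picks)
            return scores[chosen], died[chosen]
    else:
        def draw(rng: np.random.Generator):
            return simple_random_sample(scores, died, scenario.sample_size, rng,
                                        scenario.with_replacement)

    children = np.random.SeedSequence(scenario.seed).spawn(scenario.replicates)
    replicate_ws = np.empty(scenario.replicates)
    hits = 0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        s, d = draw(rng)
        result = ws_statistic(s, reference, outcomes=d)
        replicate_ws[r] = result.ws
        if result.ci_low <= target_ws <= result.ci_high:
            hits += 1
    return CoverageResult(
        population_ws=target_ws,
        replicate_ws=tuple(float(w) for w in replicate_ws),
        coverage_pct=100.0 * hits / scenario.replicates,
        mean_replicate_ws=float(replicate_ws.mean()),
    )
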