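"""Synthetic ED populations with controlled score distribution and
score-conditional survival.

Every other module can be exercised without registry data: the generator
apportions records to scores exactly (largest remainder), draws deaths as
Bernoulli(1 - Ps(score)), and can emit full vital-sign records constructed
so that scoring them with the given table returns the assigned score.
Records violating each exclusion rule can be injected to exercise the
exclusion cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .cohort_io import PatientRecord
from .sampler import largest_remainder
from .scoring import BinnedItem, CategoricalItem, ReferenceTable, ScoreTable, builtin_reference, builtin_score_table

#: finite caps for open-ended bins when drawing values uniformly
DEFAULT_VALUE_CAPS = {"age": 110.0, "sbp": 300.0, "hr": 250.0, "rr": 60.0, "spo2": 100.0}

#: (ed_result, hospital_result) pairs consistent with each outcome
_SURVIVED_RESULTS = (("discharged", "not_admitted"), ("admitted", "discharged"))
_DIED_RESULTS = (("died", "not_admitted"), ("hopeless_discharge", "not_admitted"),
                 ("admitted", "died"), ("admitted", "hopeless_discharge"))

EXCLUSION_NOISE_RULES = ("under_15", "transfer_out", "arrival_arrest",
                         "missing_variable", "implausible_sbp", "implausible_spo2")


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic population.

    Defaults mirror the built-in reference: score distribution from the
    reference stratum counts (grouped strata split uniformly over member
    scores) and survival probabilities from the reference Ps curve.
    """

    n: int
    seed: int = 0
    score_distribution: Optional[Mapping[int, float]] = None
    survival_curve: Optional[Mapping[int, float]] = None
    emit_vitals: bool = False
    exclusion_noise: float = 0.0
    value_caps: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VALUE_CAPS))

    def resolved(self) -> "GeneratorSpec":
        """Fill in defaults from the built-in reference table."""
        if self.score_distribution is not None and self.survival_curve is not None:
            return self
        ref = builtin_reference(warn_non_monotone=False)
        dist = self.score_distribution
        if dist is None:
            dist = ref.score_distribution()
        curve = self.survival_curve
        if curve is None:
            curve = {s: ref.ps(s) for s in dist}
        return replace(self, score_distribution=dist, survival_curve=curve)

    def validate(self) -> None:
        if self.n <= 0:
            raise GenerationError("n must be positive")
        if self.exclusion_noise < 0:
            raise GenerationError("exclusion_noise must be non-negative")
        dist = self.score_distribution
        if dist is not None:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise GenerationError(f"score distribution sums to {total}, expected 1")
        curve = self.survival_curve
        if curve is not None and any(not 0.0 <= p <= 1.0 for p in curve.values()):
            raise GenerationError("survival probabilities must lie in [0, 1]")


def composition_counts(table: ScoreTable) -> np.ndarray:
    """Dynamic-programming count of item-score compositions per total.

    ``result[t]`` is the number of distinct tuples of per-item score values
    summing to ``t`` (bins sharing a score value within an item count once).
    """
    counts = np.array([1], dtype=object)
    for item in table.items:
        item_scores = sorted(item.distinct_scores())
        new = np.zeros(len(counts) + max(item_scores), dtype=object)
        for s in item_scores:
            new[s:s + len(counts)] += counts
        counts = new
    return counts


def _suffix_counts(table: ScoreTable) -> list[np.ndarray]:
    """``suffix[i][t]``: compositions of items i.. summing to t."""
    suffix = [np.array([1], dtype=object)]
    for item in reversed(table.items):
        prev = suffix[0]
        item_scores = sorted(item.distinct_scores())
        new = np.zeros(len(prev) + max(item_scores), dtype=object)
        for s in item_scores:
            new[s:s + len(prev)] += prev
        suffix.insert(0, new)
    return suffix


def vitals_for_score(
    target: int,
    table: Optional[ScoreTable] = None,
    rng: Union[np.random.Generator, int, None] = None,
    value_caps: Optional[Mapping[str, float]] = None,
) -> dict:
    """Field values that score to exactly ``target`` under ``table``.

    A composition of per-item score values summing to the target is chosen
    uniformly at random among all feasible compositions (counted by dynamic
    programming over the items); each item then draws a concrete value
    uniformly inside a bin (or category) carrying its chosen score.
    Open-ended bins are capped at documented physiologic ceilings.
    """
    if table is None:
        table = builtin_score_table()
    rng = np.random.default_rng(rng)
    caps = dict(DEFAULT_VALUE_CAPS)
    if value_caps:
        caps.update(value_caps)

    suffix = _suffix_counts(table)
    if target < 0 or target >= len(suffix[0]) or suffix[0][target] == 0:
        raise GenerationError(f"score {target} has no feasible item composition")

    values: dict = {}
    remaining = target
    for i, item in enumerate(table.items):
        item_scores = sorted(item.distinct_scores())
        feasible = []
        weights = []
        for s in item_scores:
            rest = remaining - s
            if 0 <= rest < len(suffix[i + 1]) and suffix[i + 1][rest] > 0:
                feasible.append(s)
                weights.append(suffix[i + 1][rest])
        total = sum(weights)
        pick = rng.random() * float(total)
        acc = 0.0
        chosen = feasible[-1]
        for s, w in zip(feasible, weights):
            acc += float(w)
            if pick < acc:
                chosen = s
                break
        remaining -= chosen
        values[item.field] = _draw_value(item, chosen, rng, caps)
    assert remaining == 0
    return values


def _draw_value(item, score, rng: np.random.Generator, caps: Mapping[str, float]):
    if isinstance(item, CategoricalItem):
        options = sorted(cat for cat, s in item.scores.items() if s == score)
        return options[int(rng.integers(len(options)))]
    ranges = item.value_range_for_score(score)
    low, high = ranges[int(rng.integers(len(ranges)))]
    if not np.isfinite(high):
        high = caps.get(item.field, low + 50.0)
    if item.field == "age":
        # ages are integers; bins are (low, high] except the first, which
        # includes its lower endpoint
        lo = int(item.lower) if low <= item.lower else int(np.floor(low)) + 1
        return int(rng.integers(lo, int(high) + 1))
    # real-valued vitals: uniform in (low, high]
    return float(high - rng.random() * (high - low))


def _results_for_outcome(died: bool, rng: np.random.Generator) -> tuple[str, str]:
    options = _DIED_RESULTS if died else _SURVIVED_RESULTS
    return options[int(rng.integers(len(options)))]


def generate_population(spec: GeneratorSpec, table: Optional[ScoreTable] = None):
    """Generate a synthetic population.

    Returns ``(scores, died)`` integer/boolean arrays when
    ``spec.emit_vitals`` is false, else a list of :class:`PatientRecord`
    whose vitals score back to the assigned value exactly.

    Per-score counts are the largest-remainder apportionment of
    ``n x score_distribution`` — the empirical distribution matches the
    request exactly, not just in expectation.
    """
    spec = spec.resolved()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    score_values = np.array(sorted(spec.score_distribution), dtype=np.int64)
    weights = np.array([spec.score_distribution[int(s)] for s in score_values])
    counts = largest_remainder(weights, spec.n)
    scores = np.repeat(score_values, counts)

    ps = np.array([spec.survival_curve.get(int(s)) for s in score_values], dtype=object)
    if any(p is None for p in ps):
        missing = [int(s) for s, p in zip(score_values, ps) if p is None]
        raise GenerationError(f"survival curve missing scores {missing}")
    ps_per_record = np.repeat(ps.astype(float), counts)
    died = rng.random(spec.n) < (1.0 - ps_per_record)

    if not spec.emit_vitals:
        return scores, died

    if table is None:
        table = builtin_score_table()
    records = []
    for i, (score, is_dead) in enumerate(zip(scores, died)):
        fields = vitals_for_score(int(score), table, rng, spec.value_caps)
        ed_result, hospital_result = _results_for_outcome(bool(is_dead), rng)
        records.append(PatientRecord(
            id=f"syn{i:07d}",
            age=int(fields["age"]),
            sex=fields["sex"], cause=fields["cause"], avpu=fields["avpu"],
            sbp=fields["sbp"], hr=fields["hr"], rr=fields["rr"], spo2=fields["spo2"],
            dbp=float(np.clip(rng.normal(80.0, 10.0), 20.0, 150.0)),
            bt=float(np.clip(rng.normal(36.6, 0.4), 34.0, 41.0)),
            ed_result=ed_result, hospital_result=hospital_result,
        ))
    return records


def inject_exclusions(
    cohort: Sequence[PatientRecord],
    spec: GeneratorSpec,
    table: Optional[ScoreTable] = None,
) -> tuple[list[PatientRecord], dict[str, list[str]]]:
    """Append records violating each exclusion rule and shuffle.

    For each rule, ``round(exclusion_noise * len(cohort))`` violating
    records are appended.  Returns the shuffled cohort plus a log mapping
    each rule to the injected record ids, for bookkeeping in tests.
    """
    if spec.exclusion_noise < 0:
        raise GenerationError("exclusion_noise must be non-negative")
    if spec.exclusion_noise == 0:
        return list(cohort), {rule: [] for rule in EXCLUSION_NOISE_RULES}

    if table is None:
        table = builtin_score_table()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE5C]))
    per_rule = int(round(spec.exclusion_noise * len(cohort)))
    out = list(cohort)
    log: dict[str, list[str]] = {}
    counter = 0
    for rule in EXCLUSION_NOISE_RULES:
        ids = []
        for _ in range(per_rule):
            fields = vitals_for_score(int(rng.integers(0, 10)), table, rng,
                                      spec.value_caps)
            rid = f"inj{counter:06d}_{rule}"
            counter += 1
            record = PatientRecord(
                id=rid, age=int(fields["age"]), sex=fields["sex"],
                cause=fields["cause"], avpu=fields["avpu"],
                sbp=fields["sbp"], hr=fields["hr"], rr=fields["rr"], spo2=fields["spo2"],
                ed_result="discharged", hospital_result="not_admitted",
            )
            if rule == "under_15":
                record = replace(record, age=int(rng.integers(0, 15)))
            elif rule == "transfer_out":
                record = replace(record, transferred_out=True,
                                 ed_result="transferred", hospital_result="not_admitted")
            elif rule == "arrival_arrest":
                record = replace(record, arrival_arrest=True)
            elif rule == "missing_variable":
                victim = ("sbp", "hr", "rr", "spo2")[int(rng.integers(4))]
                record = replace(record, **{victim: None})
            elif rule == "implausible_sbp":
                record = replace(record, sbp=float(301 + rng.random() * 100))
            elif rule == "implausible_spo2":
                record = replace(record, spo2=float(101 + rng.random() * 5))
            ids.append(rid)
            out.append(record)
        log[rule] = ids
    order = rng.permutation(len(out))
    return [out[i] for i in order], log
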