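"""Integer bin-based severity score tables and survival reference tables.

The built-in score table and 2016-style reference table ship as packaged
JSON fixtures; :func:`builtin_score_table` and :func:`builtin_reference`
load them.  Any table with the same shape can be supplied instead (JSON or
YAML via :meth:`ScoreTable.from_dict`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import numbers
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Union

from .cohort_io import PatientRecord

log = logging.getLogger(__name__)

Number = Union[int, float]


class ScoringError(ValueError):
    """A record cannot be scored (missing field or out-of-domain value)."""


class BinGapError(ScoringError):
    """Strict-mode lookup hit a deliberately unmapped value range."""


@dataclass(frozen=True)
class CategoricalItem:
    """Score item keyed by a closed category set."""

    name: str
    field: str
    scores: Mapping[str, Number]

    def score(self, value) -> Number:
        if value is None:
            raise ScoringError(f"item {self.name!r}: required field {self.field!r} is absent")
        try:
            return self.scores[value]
        except KeyError:
            raise ScoringError(f"item {self.name!r}: unknown category {value!r}") from None

    @property
    def max_score(self) -> Number:
        return max(self.scores.values())

    @property
    def min_score(self) -> Number:
        return min(self.scores.values())

    def distinct_scores(self) -> set:
        return set(self.scores.values())

    def to_dict(self) -> dict:
        return {"name": self.name, "field": self.field, "kind": "categorical",
                "scores": dict(self.scores)}


@dataclass(frozen=True)
class BinnedItem:
    """Score item keyed by ordered half-open value bins.

    ``bins`` is a sequence of (inclusive upper bound, score); values above
    the last bound take ``above``.  ``lower`` documents the smallest valid
    value (first bin is [lower, bins[0][0]]).  ``gaps`` lists (low, high]
    ranges that raise :class:`BinGapError` — used by the strict
    respiratory-rate variant where the printed table leaves a range unmapped.
    """

    name: str
    field: str
    bins: tuple[tuple[float, Number], ...]
    above: Number
    lower: float = 0.0
    gaps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.bins]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"item {self.name!r}: bin upper bounds must be strictly increasing")

    def score(self, value) -> Number:
        if value is None:
            raise ScoringError(f"item {self.name!r}: required field {self.field!r} is absent")
        for low, high in self.gaps:
            if low < value <= high:
                raise BinGapError(
                    f"item {self.name!r}: value {value!r} falls in unmapped range ({low}, {high}]"
                )
        for upper, score in self.bins:
            if value <= upper:
                return score
        return self.above

    @property
    def max_score(self) -> Number:
        return max(self.above, *(s for _, s in self.bins))

    @property
    def min_score(self) -> Number:
        return min(self.above, *(s for _, s in self.bins))

    def distinct_scores(self) -> set:
        return {s for _, s in self.bins} | {self.above}

    def value_range_for_score(self, score: Number) -> list[tuple[float, float]]:
        """All (low, high] value intervals mapping to ``score``."""
        ranges = []
        prev = self.lower
        for upper, s in self.bins:
            if s == score:
                ranges.append((prev, upper))
            prev = upper
        if self.above == score:
            ranges.append((prev, float("inf")))
        return ranges

    def to_dict(self) -> dict:
        out = {"name": self.name, "field": self.field, "kind": "binned",
               "lower": self.lower, "bins": [[u, s] for u, s in self.bins],
               "above": self.above}
        if self.gaps:
            out["gaps"] = [[lo, hi] for lo, hi in self.gaps]
        return out


ScoreItem = Union[CategoricalItem, BinnedItem]


def _item_from_dict(data: Mapping) -> ScoreItem:
    kind = data["kind"]
    if kind == "categorical":
        return CategoricalItem(name=data["name"], field=data["field"], scores=dict(data["scores"]))
    if kind == "binned":
        return BinnedItem(
            name=data["name"], field=data["field"],
            bins=tuple((float(u), s) for u, s in data["bins"]),
            above=data["above"], lower=float(data.get("lower", 0.0)),
            gaps=tuple((float(lo), float(hi)) for lo, hi in data.get("gaps", ())),
        )
    raise ValueError(f"unknown item kind {kind!r}")


@dataclass(frozen=True)
class ScoreTable:
    """Ordered collection of score items; a record's score is the sum of
    its item scores.  All scores must be non-negative integers."""

    items: tuple[ScoreItem, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        seen = set()
        for item in self.items:
            if item.name in seen:
                raise ValueError(f"duplicate item name {item.name!r}")
            seen.add(item.name)
            for s in item.distinct_scores():
                if not (isinstance(s, numbers.Integral) and not isinstance(s, bool) and s >= 0):
                    raise ValueError(f"item {item.name!r}: scores must be non-negative integers, got {s!r}")

    def __iter__(self):
        return iter(self.items)

    def item(self, name: str) -> ScoreItem:
        for item in self.items:
            if item.name == name:
                return item
        raise KeyError(name)

    @property
    def max_score(self) -> int:
        return sum(item.max_score for item in self.items)

    @property
    def min_score(self) -> int:
        return sum(item.min_score for item in self.items)

    def score_record(self, record: PatientRecord) -> int:
        """Total score for one record; raises :class:`ScoringError` if a
        required field is absent."""
        return sum(item.score(_field_value(record, item.field)) for item in self.items)

    def score_cohort(self, records: Iterable[PatientRecord]) -> list[int]:
        return [self.score_record(r) for r in records]

    def to_dict(self) -> dict:
        return {"name": self.name, "items": [item.to_dict() for item in self.items]}

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScoreTable":
        return cls(items=tuple(_item_from_dict(d) for d in data["items"]),
                   name=data.get("name", "custom"))

    def checksum(self) -> str:
        """sha256 over the canonical JSON form, for provenance reporting."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _field_value(record, field_name: str):
    if isinstance(record, Mapping):
        return record.get(field_name)
    return getattr(record, field_name)


def score_record(table: ScoreTable, record: PatientRecord) -> int:
    """Functional alias for :meth:`ScoreTable.score_record`."""
    return table.score_record(record)


@dataclass(frozen=True)
class Stratum:
    """A severity stratum: contiguous group of score values with its
    reference count and fraction."""

    label: str
    scores: tuple[int, ...]
    count: float
    fraction: float


@dataclass(frozen=True)
class ReferenceTable:
    """Predicted survival probability per score plus the reference severity
    distribution used for standardization.

    ``ps_by_score`` covers individual scores below ``top_ps_min_score``;
    scores at or above it share ``top_ps`` (the grouped top bucket).  Absent
    entries (``None``) are allowed for derived tables with empty buckets and
    raise on lookup.
    """

    ps_by_score: Mapping[int, Optional[float]]
    top_ps: Optional[float]
    top_ps_min_score: int
    strata: tuple[Stratum, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        for score, ps in self.ps_by_score.items():
            if ps is not None and not 0.0 <= ps <= 1.0:
                raise ValueError(f"Ps({score}) = {ps} outside [0, 1]")
        total = sum(s.fraction for s in self.strata)
        if self.strata and abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum fractions sum to {total}, expected 1")
        covered: set[int] = set()
        for stratum in self.strata:
            overlap = covered & set(stratum.scores)
            if overlap:
                raise ValueError(f"strata overlap on scores {sorted(overlap)}")
            covered |= set(stratum.scores)

    def ps(self, score: int) -> float:
        """Predicted survival probability for a score value."""
        if score >= self.top_ps_min_score:
            value = self.top_ps
        else:
            value = self.ps_by_score.get(score)
        if value is None:
            raise KeyError(f"no survival probability for score {score}")
        return value

    def has_ps(self, score: int) -> bool:
        try:
            self.ps(score)
            return True
        except KeyError:
            return False

    def stratum_of(self, score: int) -> Stratum:
        for stratum in self.strata:
            if score in stratum.scores:
                return stratum
        raise KeyError(f"score {score} outside reference strata")

    @property
    def total_count(self) -> float:
        return sum(s.count for s in self.strata)

    @property
    def non_monotone_scores(self) -> tuple[int, ...]:
        """Scores where Ps increases relative to the previous score (the
        printed fixture has one such anomaly, kept as printed)."""
        scores = sorted(s for s in self.ps_by_score if self.ps_by_score[s] is not None)
        out = []
        for prev, cur in zip(scores, scores[1:]):
            if self.ps_by_score[cur] > self.ps_by_score[prev]:
                out.append(cur)
        return tuple(out)

    def expanded_counts(self, top_scores: Sequence[int] = (19, 20, 21, 22)) -> dict[int, float]:
        """Per-score counts with grouped strata split uniformly over member
        scores.  The open-ended top stratum is spread over ``top_scores``
        (default: the scores carrying distinct survival probabilities plus
        the grouped top bucket); counts may be fractional."""
        counts: dict[int, float] = {}
        for stratum in self.strata:
            members = stratum.scores
            if members[-1] >= self.top_ps_min_score:
                # open-ended top stratum: spread over the designated scores
                members = tuple(s for s in top_scores if s >= members[0]) or members[:1]
            share = stratum.count / len(members)
            for s in members:
                counts[s] = counts.get(s, 0.0) + share
        return counts

    def score_distribution(self, top_scores: Sequence[int] = (19, 20, 21, 22)) -> dict[int, float]:
        counts = self.expanded_counts(top_scores)
        total = sum(counts.values())
        return {s: c / total for s, c in counts.items()}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "ps_by_score": {str(k): v for k, v in sorted(self.ps_by_score.items())},
            "top_ps_min_score": self.top_ps_min_score,
            "top_ps": self.top_ps,
            "strata": [
                {"label": s.label, "scores": list(s.scores), "count": s.count, "fraction": s.fraction}
                for s in self.strata
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping, fractions_from_counts: bool = True) -> "ReferenceTable":
        strata_raw = data["strata"]
        total = sum(s["count"] for s in strata_raw)
        strata = tuple(
            Stratum(
                label=s["label"],
                scores=tuple(s["scores"]),
                count=s["count"],
                fraction=(s["count"] / total) if fractions_from_counts else s["fraction"],
            )
            for s in strata_raw
        )
        return cls(
            ps_by_score={int(k): v for k, v in data["ps_by_score"].items()},
            top_ps=data.get("top_ps"),
            top_ps_min_score=int(data["top_ps_min_score"]),
            strata=strata,
            name=data.get("name", "custom"),
        )

    def checksum(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _load_data(filename: str) -> dict:
    with resources.files("edies._data").joinpath(filename).open("rb") as handle:
        return json.load(handle)


def builtin_score_table(strict_rr: bool = False) -> ScoreTable:
    """The built-in eight-item score table (total range 0–39).

    The published respiratory-rate bins leave (33, 35] unmapped; by default
    the final bin is read as ``>33``.  With ``strict_rr=True`` the gap is
    reproduced and scoring a value inside it raises :class:`BinGapError`.
    """
    table = ScoreTable.from_dict(_load_data("edies_table.json"))
    if not strict_rr:
        return table
    items = []
    for item in table.items:
        if item.name == "rr":
            item = BinnedItem(name=item.name, field=item.field, bins=item.bins,
                              above=item.above, lower=item.lower, gaps=((33.0, 35.0),))
        items.append(item)
    return ScoreTable(items=tuple(items), name=table.name + "-strict-rr")


#: alias matching the historical name of the built-in system
builtin_edies = builtin_score_table


def builtin_reference(warn_non_monotone: bool = True) -> ReferenceTable:
    """The built-in reference table: per-score survival probabilities and
    the 19-stratum severity distribution (N = 1,836,577).

    The stored fractions are renormalized from the stratum counts (the
    printed 4-decimal fractions are kept in the data file for integrity
    checks).  One survival probability breaks monotonicity as printed; a
    warning is emitted unless suppressed.
    """
    ref = ReferenceTable.from_dict(_load_data("reference_2016.json"))
    if warn_non_monotone and ref.non_monotone_scores:
        warnings.warn(
            f"reference survival probabilities are non-monotone at scores "
            f"{ref.non_monotone_scores} (kept as printed)",
            UserWarning, stacklevel=2,
        )
    return ref


def builtin_printed_fractions() -> dict[str, float]:
    """The printed 4-decimal stratum fractions (for integrity checks)."""
    data = _load_data("reference_2016.json")
    return {s["label"]: s["printed_fraction"] for s in data["strata"]}


DEFAULT_STRATA_SPEC: tuple[tuple[int, ...], ...] = tuple(
    [(s,) for s in range(17)] + [(17, 18), tuple(range(19, 40))]
)


def derive_reference(
    scored_cohort: Sequence[tuple[int, str]],
    strata_spec: Sequence[Sequence[int]] = DEFAULT_STRATA_SPEC,
    ps_buckets: Optional[Sequence[Sequence[int]]] = None,
    name: str = "derived",
) -> ReferenceTable:
    """Build a reference table from a scored cohort.

    Parameters
    ----------
    scored_cohort : sequence of (score, outcome)
        Outcome is ``"survived"``/``"died"``.
    strata_spec : sequence of score groups
        Severity strata (default: single scores 0–16, {17, 18}, {>=19}).
    ps_buckets : sequence of score groups, optional
        Buckets over which survival proportions are pooled.  Default:
        each score 0–21 alone plus a grouped {>=22} bucket.

    Survival per bucket is the observed proportion of survivors; empty
    buckets yield an absent probability with a warning.
    """
    if not len(scored_cohort):
        raise ValueError("cannot derive a reference from an empty cohort")
    if ps_buckets is None:
        ps_buckets = [(s,) for s in range(22)] + [tuple(range(22, 40))]

    totals: dict[int, int] = {}
    survivors: dict[int, int] = {}
    for score, outcome in scored_cohort:
        score = int(score)
        totals[score] = totals.get(score, 0) + 1
        if outcome == "survived":
            survivors[score] = survivors.get(score, 0) + 1

    top_bucket = max(ps_buckets, key=lambda b: max(b))
    top_min = min(top_bucket)
    ps_by_score: dict[int, Optional[float]] = {}
    top_ps: Optional[float] = None
    for bucket in ps_buckets:
        n = sum(totals.get(s, 0) for s in bucket)
        k = sum(survivors.get(s, 0) for s in bucket)
        value = (k / n) if n else None
        if value is None:
            warnings.warn(f"empty survival bucket {tuple(bucket)}; probability left absent",
                          UserWarning, stacklevel=2)
        if bucket is top_bucket:
            top_ps = value
        else:
            for s in bucket:
                ps_by_score[s] = value

    total_n = len(scored_cohort)
    strata = []
    for group in strata_spec:
        group = tuple(int(s) for s in group)
        n = sum(totals.get(s, 0) for s in group)
        label = str(group[0]) if len(group) == 1 else (
            f">={group[0]}" if group[-1] >= 39 else f"{group[0]}-{group[-1]}")
        strata.append(Stratum(label=label, scores=group, count=n, fraction=n / total_n))
    return ReferenceTable(
        ps_by_score=ps_by_score, top_ps=top_ps, top_ps_min_score=top_min,
        strata=tuple(strata), name=name,
    )
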