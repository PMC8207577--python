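"""W and standardized W (Ws) statistics with 95% confidence intervals.

W is the excess number of survivors per 100 patients relative to the
reference prediction.  Ws standardizes W over severity strata: the
per-stratum W values are averaged with the *reference* population's stratum
fractions, removing case-mix differences between the cohort under study and
the reference.

The interval variance treats each patient's survival as Bernoulli with the
predicted probability (null-model variance); an observed-proportion variant
is available for sensitivity analysis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .scoring import ReferenceTable, Stratum

Z_95 = 1.96  # fixed two-sided 95% level


class WsError(ValueError):
    pass


class DomainError(WsError):
    """A cohort score has no survival probability or stratum in the reference."""


def w_statistic(n: int, observed_survivors: float, expected_survivors: float) -> float:
    """Excess survivors per 100 patients: ``100 * (O - E) / n``."""
    if n <= 0:
        raise WsError("W statistic undefined for an empty group")
    if not (0 <= observed_survivors <= n and 0 <= expected_survivors <= n):
        raise WsError("survivor counts must lie in [0, n]")
    return 100.0 * (observed_survivors - expected_survivors) / n


@dataclass(frozen=True)
class StratumSummary:
    """Per-stratum ingredients of Ws.

    ``observed`` is real-valued so analytically self-consistent populations
    (observed set equal to expected) can be expressed exactly; cohort entry
    points always produce integer values.  ``var_term`` is the summed
    per-patient Bernoulli variance Σ p(1-p) used in the CI.
    """

    label: str
    n: int
    observed: float
    expected: float
    var_term: float
    fraction: float

    @property
    def w(self) -> float:
        return w_statistic(self.n, self.observed, self.expected)

    @property
    def var_w(self) -> float:
        return (100.0 / self.n) ** 2 * self.var_term

    def to_dict(self) -> dict:
        return {
            "stratum": self.label, "n": self.n,
            "observed_survivors": self.observed, "expected_survivors": self.expected,
            "w": self.w, "var_w": self.var_w, "reference_fraction": self.fraction,
        }


@dataclass(frozen=True)
class WsResult:
    """Ws point estimate with its 95% CI and the per-stratum breakdown."""

    ws: float
    se: float
    ci_low: float
    ci_high: float
    overall_w: float
    strata: tuple[StratumSummary, ...]
    renormalized: bool = False

    def to_dict(self) -> dict:
        return {
            "ws": self.ws, "se": self.se,
            "ci_95": [self.ci_low, self.ci_high],
            "overall_w": self.overall_w,
            "renormalized": self.renormalized,
            "strata": [s.to_dict() for s in self.strata],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _coerce_scored(cohort_or_scores, outcomes=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a sequence of (score, outcome) pairs or parallel
    score/outcome arrays; returns (scores int array, survived bool array)."""
    if outcomes is None:
        pairs = list(cohort_or_scores)
        scores = np.array([int(s) for s, _ in pairs], dtype=np.int64)
        raw = [o for _, o in pairs]
    else:
        scores = np.asarray(cohort_or_scores, dtype=np.int64)
        raw = outcomes
    if isinstance(raw, np.ndarray) and raw.dtype == bool:
        # boolean convention: True means died
        survived = ~raw
    else:
        survived = np.array([o == "survived" for o in raw], dtype=bool)
    if scores.shape != survived.shape:
        raise WsError("scores and outcomes must have equal length")
    return scores, survived


def _reference_arrays(reference: ReferenceTable, max_score: int = 39):
    """Dense per-score lookup arrays: Ps, stratum index, validity mask."""
    size = max_score + 1
    ps = np.full(size, np.nan)
    stratum_idx = np.full(size, -1, dtype=np.int64)
    for j, stratum in enumerate(reference.strata):
        for s in stratum.scores:
            if s < size:
                stratum_idx[s] = j
    for s in range(size):
        if reference.has_ps(s):
            ps[s] = reference.ps(s)
    return ps, stratum_idx


def ws_statistic(
    cohort_or_scores,
    reference: ReferenceTable,
    outcomes=None,
    variance: str = "predicted",
) -> WsResult:
    """Compute Ws for a scored cohort against a reference table.

    Parameters
    ----------
    cohort_or_scores
        Either a sequence of ``(score, outcome)`` pairs or an array of
        scores (then ``outcomes`` must be given: outcome strings, or a
        boolean array where True means died).
    reference
        Supplies Ps per score, the strata, and the standardizing fractions.
    variance : {"predicted", "observed"}
        CI variance from predicted probabilities Σ p(1-p) (default) or from
        the observed stratum proportion (sensitivity variant).

    Empty reference strata are dropped and the remaining fractions
    renormalized (flagged on the result with a warning).
    """
    if variance not in ("predicted", "observed"):
        raise ValueError(f"unknown variance mode {variance!r}")
    scores, survived = _coerce_scored(cohort_or_scores, outcomes)
    if scores.size == 0:
        raise WsError("cannot compute Ws for an empty cohort")

    ps_lut, stratum_lut = _reference_arrays(reference)
    if scores.min() < 0 or scores.max() >= ps_lut.size:
        bad = int(scores.min()) if scores.min() < 0 else int(scores.max())
        raise DomainError(f"score {bad} outside the reference domain")
    idx = stratum_lut[scores]
    if (idx < 0).any():
        bad = int(scores[idx < 0][0])
        raise DomainError(f"score {bad} not covered by any reference stratum")
    ps = ps_lut[scores]
    if np.isnan(ps).any():
        bad = int(scores[np.isnan(ps)][0])
        raise DomainError(f"no survival probability for score {bad}")

    n_strata = len(reference.strata)
    n_j = np.bincount(idx, minlength=n_strata).astype(np.int64)
    obs_j = np.bincount(idx, weights=survived.astype(float), minlength=n_strata)
    exp_j = np.bincount(idx, weights=ps, minlength=n_strata)
    var_j = np.bincount(idx, weights=ps * (1.0 - ps), minlength=n_strata)
    if variance == "observed":
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = np.where(n_j > 0, obs_j / np.maximum(n_j, 1), 0.0)
        var_j = n_j * phat * (1.0 - phat)

    fractions = np.array([s.fraction for s in reference.strata])
    populated = n_j > 0
    renormalized = bool((~populated & (fractions > 0)).any())
    if renormalized:
        warnings.warn(
            "empty reference strata dropped; fractions renormalized over populated strata",
            UserWarning, stacklevel=2,
        )
    weight = np.where(populated, fractions, 0.0)
    total_weight = weight.sum()
    if total_weight <= 0:
        raise WsError("all populated strata carry zero reference weight")
    weight = weight / total_weight

    summaries = tuple(
        StratumSummary(
            label=reference.strata[j].label,
            n=int(n_j[j]),
            observed=float(obs_j[j]),
            expected=float(exp_j[j]),
            var_term=float(var_j[j]),
            fraction=float(weight[j]),
        )
        for j in range(n_strata)
        if populated[j]
    )

    ws = float(sum(s.fraction * s.w for s in summaries))
    var = float(sum(s.fraction ** 2 * s.var_w for s in summaries))
    se = math.sqrt(var)
    overall_w = w_statistic(int(n_j.sum()), float(obs_j.sum()), float(exp_j.sum()))
    return WsResult(
        ws=ws, se=se, ci_low=ws - Z_95 * se, ci_high=ws + Z_95 * se,
        overall_w=overall_w, strata=summaries, renormalized=renormalized,
    )


def ws_from_summaries(summaries: Sequence[StratumSummary]) -> WsResult:
    """Assemble a Ws result from pre-built stratum summaries (fractions must
    sum to 1).  Used for analytic self-consistency checks."""
    total = sum(s.fraction for s in summaries)
    if abs(total - 1.0) > 1e-9:
        raise WsError(f"stratum fractions sum to {total}, expected 1")
    ws = float(sum(s.fraction * s.w for s in summaries))
    se = math.sqrt(sum(s.fraction ** 2 * s.var_w for s in summaries))
    n_total = sum(s.n for s in summaries)
    overall_w = w_statistic(n_total, sum(s.observed for s in summaries),
                            sum(s.expected for s in summaries))
    return WsResult(ws=ws, se=se, ci_low=ws - Z_95 * se, ci_high=ws + Z_95 * se,
                    overall_w=overall_w, strata=tuple(summaries), renormalized=False)


def self_consistent_ws(
    reference: ReferenceTable,
    counts_by_score: Optional[Mapping[int, float]] = None,
) -> WsResult:
    """Ws of a population whose observed survivors equal the reference
    expectation exactly, stratum by stratum.

    ``counts_by_score`` defaults to the reference's own expanded per-score
    counts.  Observed survivors are set to Σ n_s Ps(s), so every stratum W
    is exactly zero and Ws is 0; the CI width is still informative.
    """
    if counts_by_score is None:
        counts_by_score = reference.expanded_counts()
    summaries = []
    for stratum in reference.strata:
        members = [s for s in counts_by_score if s in stratum.scores]
        n = sum(counts_by_score[s] for s in members)
        if n <= 0:
            continue
        expected = sum(counts_by_score[s] * reference.ps(s) for s in members)
        var_term = sum(counts_by_score[s] * reference.ps(s) * (1.0 - reference.ps(s))
                       for s in members)
        summaries.append(StratumSummary(
            label=stratum.label, n=n, observed=expected,
            expected=expected, var_term=var_term, fraction=stratum.fraction,
        ))
    return ws_from_summaries(summaries)
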