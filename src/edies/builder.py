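"""Rebuild an integer score table from data.

Pipeline: user-assigned arbitrary bin scores per variable -> maximum
likelihood logistic regression of mortality on the item scores -> final
integer bin score = round(2 x coefficient x arbitrary score), half away
from zero.  AUROC (Mann-Whitney form) validates the resulting score.

The optimizer is a damped Newton iteration on the Bernoulli log-likelihood:
deterministic, no randomness, convergence when the max absolute score
equation residual drops below 1e-8.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .scoring import BinnedItem, CategoricalItem, ScoreItem, ScoreTable

GRADIENT_TOL = 1e-8
MAX_ITER = 100


class FitError(ValueError):
    pass


class SeparationError(FitError):
    """The likelihood has no finite maximizer (complete separation)."""


class MappingError(ValueError):
    """Fitted items and bin-spec items do not match."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression result (outcome = death)."""

    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    intercept_se: float
    converged: bool
    n_iterations: int
    log_likelihood: float

    def to_dict(self) -> dict:
        rows = [{"parameter": "(intercept)", "coefficient": self.intercept,
                 "standard_error": self.intercept_se}]
        for name in self.coefficients:
            rows.append({"parameter": name, "coefficient": self.coefficients[name],
                         "standard_error": self.standard_errors[name]})
        return {"converged": self.converged, "n_iterations": self.n_iterations,
                "log_likelihood": self.log_likelihood, "parameters": rows}


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: -log(1 + exp(-eta)) on y=1, -log(1 + exp(eta)) on y=0
    return float(-np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta))))


def fit_logistic(
    design,
    outcomes=None,
    item_names: Optional[Sequence[str]] = None,
    max_iter: int = MAX_ITER,
    tol: float = GRADIENT_TOL,
) -> LogisticFit:
    """Fit mortality ~ item scores by damped Newton maximum likelihood.

    ``design`` is either a sequence of ``(vector, outcome)`` pairs or an
    (n, p) array (then ``outcomes`` holds ``"died"``/``"survived"`` strings,
    or 0/1 with 1 = died).  An intercept is always included.

    Raises
    ------
    FitError
        Constant outcome, or an item constant across records.
    SeparationError
        Complete separation (no finite maximum); diagnostic included.
    """
    if outcomes is None:
        pairs = list(design)
        X = np.asarray([np.atleast_1d(v) for v, _ in pairs], dtype=float)
        raw = [o for _, o in pairs]
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        raw = outcomes
    if X.ndim != 2:
        raise FitError("design must be a 2-D array of item scores")
    y = np.array([1.0 if o in (1, True, "died") else 0.0 for o in raw])
    n, p = X.shape
    if y.size != n:
        raise FitError("design and outcomes must have equal length")
    if len(np.unique(y)) < 2:
        raise FitError("outcome is constant; both classes are required")
    for j in range(p):
        if np.ptp(X[:, j]) == 0.0:
            raise FitError(f"item column {j} is constant across all records")
    if item_names is None:
        item_names = [f"x{j}" for j in range(p)]
    elif len(item_names) != p:
        raise FitError("item_names length must match the number of columns")

    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    ll = _log_likelihood(Z @ beta, y)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        hess = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix; data may be completely separated"
            ) from None
        # damping: halve the step until the likelihood does not decrease
        scale = 1.0
        for _ in range(40):
            candidate = beta + scale * step
            new_ll = _log_likelihood(Z @ candidate, y)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = new_ll

    eta = Z @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.max(np.abs(y - mu)) < 1e-3:
        # the likelihood has been driven to ~0: every record fitted exactly
        raise SeparationError(
            f"complete separation: fitted probabilities match the outcomes "
            f"exactly after {iterations} iterations "
            f"(max |coefficient| = {np.max(np.abs(beta)):.1f}, no finite MLE)"
        )
    if not converged:
        fitted_extreme = float(np.mean((mu < 1e-8) | (mu > 1 - 1e-8)))
        if fitted_extreme > 0.5 or np.max(np.abs(beta)) > 30:
            raise SeparationError(
                f"no convergence after {max_iter} iterations; "
                f"{100 * fitted_extreme:.0f}% of fitted probabilities are at 0/1 "
                f"and max |coefficient| = {np.max(np.abs(beta)):.1f} — "
                "the classes appear completely separated"
            )

    w = mu * (1.0 - mu)
    hess = (Z * w[:, None]).T @ Z
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(item_names, beta[1:])},
        standard_errors={name: float(s) for name, s in zip(item_names, se[1:])},
        intercept_se=float(se[0]),
        converged=converged,
        n_iterations=iterations,
        log_likelihood=float(_log_likelihood(eta, y)),
    )


@dataclass(frozen=True)
class BinSpec:
    """Per-item bins with user-assigned arbitrary scores (any non-negative
    reals); same shape as :class:`ScoreTable` without the integer constraint."""

    items: tuple[ScoreItem, ...]

    def __iter__(self):
        return iter(self.items)

    @classmethod
    def from_dict(cls, data: Mapping) -> "BinSpec":
        from .scoring import _item_from_dict
        return cls(items=tuple(_item_from_dict(d) for d in data["items"]))

    def to_dict(self) -> dict:
        return {"items": [item.to_dict() for item in self.items]}


def round_half_away(x: float) -> int:
    """Round to the nearest integer, exact halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def integerize(fit: LogisticFit, bin_spec: BinSpec, name: str = "built") -> ScoreTable:
    """Final integer score per bin: round(2 x coefficient x arbitrary score).

    Negative products are floored at 0 with a warning.  Every item in the
    bin spec must carry a fitted coefficient.
    """
    if not fit.converged:
        raise FitError("cannot integerize a non-converged fit")
    items: list[ScoreItem] = []
    clipped: list[str] = []

    def final(item_name: str, coef: float, arbitrary: float) -> int:
        value = round_half_away(2.0 * coef * arbitrary)
        if value < 0:
            clipped.append(item_name)
            return 0
        return value

    for item in bin_spec.items:
        if item.name not in fit.coefficients:
            raise MappingError(f"item {item.name!r} has no fitted coefficient")
        coef = fit.coefficients[item.name]
        if isinstance(item, CategoricalItem):
            items.append(CategoricalItem(
                name=item.name, field=item.field,
                scores={cat: final(item.name, coef, s) for cat, s in item.scores.items()},
            ))
        else:
            items.append(BinnedItem(
                name=item.name, field=item.field,
                bins=tuple((u, final(item.name, coef, s)) for u, s in item.bins),
                above=final(item.name, coef, item.above),
                lower=item.lower, gaps=item.gaps,
            ))
    if clipped:
        warnings.warn(f"negative products floored at 0 for items: {sorted(set(clipped))}",
                      UserWarning, stacklevel=2)
    return ScoreTable(items=tuple(items), name=name)


def auroc(scores, outcomes) -> float:
    """Mann-Whitney AUROC: probability that a random death outscores a
    random survivor, ties counted one half.

    ``outcomes`` holds ``"died"``/``"survived"`` strings or a boolean array
    with True = died; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    if isinstance(outcomes, np.ndarray) and outcomes.dtype == bool:
        died = outcomes
    else:
        died = np.array([o in (1, True, "died") for o in outcomes], dtype=bool)
    if scores.shape != died.shape:
        raise ValueError("scores and outcomes must have equal length")
    n_pos = int(died.sum())
    n_neg = int(died.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both outcome classes")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    rank_sum = float(ranks[died].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
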