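"""Partial rank correlation coefficients and their validity diagnostics.

PRCC measures the monotone association between one sampled parameter and a
model output after removing the (linear-in-ranks) influence of every other
sampled parameter: both the parameter column and the output are rank
transformed (midranks for ties -- the study's output rounding makes ties
routine), each is regressed on all remaining rank columns plus an intercept,
and the coefficient is the Pearson correlation of the two residual vectors.
This equals the classical partial-correlation-matrix formula but is
numerically stabler with heavily tied ranks; the matrix-inversion route is
kept as an independent test oracle.

Validity gates implemented alongside: the inter-parameter PRCC screen (no
hidden monotone relationships among the inputs, |rho_ij| < 0.5) and the
one-at-a-time monotonicity scan that PRCC requires of each parameter/output
pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .dynamics import IntegrationError, integrate_to_steady_state
from .model import ParamRange, TreatmentGroup

__all__ = [
    "PRCCResult",
    "MonotonicityReport",
    "CollinearityError",
    "rank_transform",
    "partial_rank_correlation",
    "prcc_all",
    "interparameter_prcc",
    "classify_significance",
    "monotonicity_scan",
]

#: Default significance cutoff on |rho|.
DEFAULT_THRESHOLD = 0.5


class CollinearityError(ValueError):
    """Regressor matrix is singular after ranking; names the offending columns."""


@dataclass(frozen=True)
class PRCCResult:
    """PRCC of every varied parameter against one output under one group."""

    output_name: str
    group: TreatmentGroup | None
    rho: dict
    threshold: float = DEFAULT_THRESHOLD

    @property
    def significant(self) -> dict:
        return {k: abs(v) >= self.threshold for k, v in self.rho.items()}


@dataclass(frozen=True)
class MonotonicityReport:
    """One-at-a-time sweep of a single parameter, with rounded outputs."""

    parameter: str
    grid: np.ndarray
    outputs: dict          # output name -> rounded steady-state values on the grid
    monotone: dict         # output name -> bool (nonstrict, on rounded values)
    direction: dict        # output name -> "increasing" | "decreasing" | "flat"
    negative_values: bool
    failures: tuple = ()   # grid indices where integration failed

    @property
    def all_monotone(self) -> bool:
        return all(self.monotone.values())


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..N with ties given the average of the tied positions."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("rank_transform requires finite values")
    return rankdata(values, method="average")


def _residuals(target: np.ndarray, regressors: np.ndarray, names: Sequence[str]):
    """Residual of an intercept + least-squares fit; errors if singular."""
    n = len(target)
    Z = np.column_stack([np.ones(n), regressors])
    coef, _, rank, _ = np.linalg.lstsq(Z, target, rcond=None)
    if rank < Z.shape[1]:
        corr = np.corrcoef(regressors, rowvar=False)
        pairs = [
            (names[a], names[b])
            for a in range(len(names)) for b in range(a + 1, len(names))
            if abs(corr[a, b]) > 1 - 1e-12
        ] if len(names) > 1 else []
        raise CollinearityError(
            f"singular regressor matrix; collinear columns: {pairs or names}")
    return target - Z @ coef


def partial_rank_correlation(X: np.ndarray, y: np.ndarray, j: int,
                             names: Sequence[str] | None = None) -> float:
    """PRCC of (already ranked) column ``j`` of ``X`` against ranked ``y``.

    Requires N >= K + 2 rows.  Raises :class:`CollinearityError` when the
    controlling columns are collinear after ranking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need N >= K+2 rows for PRCC, got N={n}, K={k}")
    others = [i for i in range(k) if i != j]
    names = list(names) if names is not None else [f"x{i}" for i in range(k)]
    other_names = [names[i] for i in others]
    rx = _residuals(X[:, j], X[:, others], other_names)
    ry = _residuals(y, X[:, others], other_names)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx == 0 or sy == 0:
        raise CollinearityError(
            f"zero residual variance for column {names[j]!r}; the column or the "
            "output is fully explained by the controlling columns")
    return float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))


def prcc_all(X: np.ndarray, y: np.ndarray,
             names: Sequence[str] | None = None) -> dict:
    """PRCC of every column of a raw sample matrix against a raw output.

    Ranks are taken here (midranks); returns ``{name: rho}`` in column order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    Xr = np.column_stack([rank_transform(X[:, j]) for j in range(X.shape[1])])
    yr = rank_transform(y)
    return {names[j]: partial_rank_correlation(Xr, yr, j, names)
            for j in range(X.shape[1])}


def interparameter_prcc(X: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
    """K x K matrix of pairwise PRCCs among the sampled columns.

    Entry (i, j) is the partial rank correlation of columns i and j
    controlling for the remaining K-2 columns; the matrix is symmetric with
    unit diagonal.  A perfectly rank-correlated pair is returned as +/-1
    (with a warning) before the regression, since such a pair makes the
    remaining system singular.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(k)]
    Xr = np.column_stack([rank_transform(X[:, j]) for j in range(k)])
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ri, rj = Xr[:, i], Xr[:, j]
            c = np.corrcoef(ri, rj)[0, 1]
            if abs(c) > 1 - 1e-12:
                warnings.warn(f"columns {names[i]!r} and {names[j]!r} are perfectly "
                              "rank-correlated", stacklevel=2)
                rho = float(np.sign(c))
            elif k == 2:
                rho = float(c)  # nothing to partial out: Spearman correlation
            else:
                others = [m for m in range(k) if m not in (i, j)]
                Z = np.column_stack([np.ones(n), Xr[:, others]])
                coef_i = np.linalg.lstsq(Z, ri, rcond=None)[0]
                coef_j = np.linalg.lstsq(Z, rj, rcond=None)[0]
                ui, uj = ri - Z @ coef_i, rj - Z @ coef_j
                rho = float(np.clip(ui @ uj / (np.linalg.norm(ui) * np.linalg.norm(uj)),
                                    -1.0, 1.0))
            out[i, j] = out[j, i] = rho
    return out


def classify_significance(result: PRCCResult) -> set:
    """Names whose |rho| meets the cutoff (sign stays available in ``rho``)."""
    return {name for name, r in result.rho.items() if abs(r) >= result.threshold}


def monotonicity_scan(
    baseline,
    ranges: Sequence[ParamRange],
    group: TreatmentGroup,
    points_per_param: int = 50,
    t_end: float = 10000.0,
) -> list[MonotonicityReport]:
    """One-at-a-time sweeps validating PRCC's monotonicity requirement.

    For each varied parameter, the rounded steady-state outputs are evaluated
    on an even grid over its range with all other parameters at baseline.
    A sweep is monotone when the rounded output sequence is entirely
    nonincreasing or nondecreasing (nonstrict: rounding produces plateaus).
    Negative state excursions anywhere on the sweep are flagged.  Failed
    integrations are recorded and skipped, not fatal.
    """
    if points_per_param < 3:
        raise ValueError("points_per_param must be >= 3")
    out_names = ("E", "S") if group.frame == "dimensional" else ("e", "s")
    reports = []
    for r in ranges:
        if not r.varied:
            continue
        if not (r.lo < r.hi):
            raise ValueError(f"degenerate range for {r.name}")
        grid = np.linspace(r.lo, r.hi, points_per_param)
        vals = {name: [] for name in out_names}
        failures = []
        negative = False
        for idx, v in enumerate(grid):
            params = baseline.replace(**{r.name: float(v)})
            try:
                res = integrate_to_steady_state(group, params, t_end=t_end)
            except IntegrationError:
                failures.append(idx)
                for name in out_names:
                    vals[name].append(np.nan)
                continue
            vals[out_names[0]].append(res.rounded_E)
            vals[out_names[1]].append(res.rounded_S)
            negative = negative or res.negative_excursion or res.rounded_E < 0 or res.rounded_S < 0
        monotone, direction = {}, {}
        for name in out_names:
            seq = np.asarray(vals[name])
            ok = seq[np.isfinite(seq)]
            d = np.diff(ok)
            inc, dec = np.all(d >= 0), np.all(d <= 0)
            monotone[name] = bool(inc or dec)
            direction[name] = ("flat" if inc and dec else
                               "increasing" if inc else
                               "decreasing" if dec else "non-monotone")
        reports.append(MonotonicityReport(
            parameter=r.name, grid=grid,
            outputs={k: np.asarray(v) for k, v in vals.items()},
            monotone=monotone, direction=direction,
            negative_values=negative, failures=tuple(failures)))
    return reports
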