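"""One-parameter bifurcation analysis in cell-cell contact or TGF-beta.

The switch model's equilibria form an S-shaped curve against either input:
losing contact destroys the epithelial (high-E) state at a saddle-node fold
L_M, regaining it restores the state at a second fold L_E (a reversible
switch with hysteresis), while sweeping TGF-beta at intermediate contact
produces a single fold whose return branch would require negative TGF-beta
(an irreversible switch).

Folds are located by bisection on the equilibrium count followed by a
tangency polish: at a fold the reduced scalar residual g(S) and its
derivative g'(S) vanish together, so the polished (control, S) double root
gives the fold coordinates to root-solver precision.  This is simpler than
pseudo-arclength continuation and adequate for a two-state model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from .dynamics import EquilibriumBoundsError, find_equilibria, kinetics_for, _scalar_reduction
from .model import DimensionalParams, NondimParams, hill

__all__ = [
    "FoldPoint",
    "BifurcationDiagram",
    "SwitchClassification",
    "trace_branches",
    "locate_fold",
    "classify_switch",
    "FoldBracketError",
]

#: Default bisection tolerance on the control parameter, per control type.
FOLD_TOL = {"contact": 1e-8, "tgfb": 1e-13}


class FoldBracketError(ValueError):
    """The supplied bracket does not contain a change in equilibrium count."""


@dataclass(frozen=True)
class FoldPoint:
    """A saddle-node: control value plus the merging (double-root) state."""

    control_value: float
    E: float
    S: float


@dataclass(frozen=True)
class BifurcationDiagram:
    """Equilibrium branches against one control input.

    ``points`` has columns (control, E, S, stability, branch_id); ``folds``
    lists the saddle-node points found inside the scanned interval.
    """

    control: str  # "contact" | "tgfb"
    frozen_value: float
    frame: str
    points: pd.DataFrame
    folds: tuple

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


@dataclass(frozen=True)
class SwitchClassification:
    """Hysteresis class of a one-input sweep."""

    kind: str  # "none" | "reversible" | "irreversible"
    thresholds: tuple


def _inputs(control: str, value: float, frozen_value: float) -> tuple:
    if control == "contact":
        return value, frozen_value
    if control == "tgfb":
        return frozen_value, value
    raise ValueError(f"control must be 'contact' or 'tgfb', got {control!r}")


def _count(params, control, value, frozen_value, n_grid=2000) -> int:
    c, t = _inputs(control, value, frozen_value)
    return len(find_equilibria(params, c, t, n_grid=n_grid))


def locate_fold(
    params: DimensionalParams | NondimParams,
    control: str,
    frozen_value: float,
    bracket: Sequence[float],
    tol: float | None = None,
) -> FoldPoint:
    """Locate a saddle-node inside ``bracket = (lo, hi)`` on the control axis.

    Bisects on the equilibrium count until the bracket is below ``tol``
    (1e-8 in contact, 1e-13 in TGF-beta by default), then polishes the
    tangency system g(S; c) = g'(S; c) = 0 for the double root.
    """
    tol = FOLD_TOL[control] * max(1.0, abs(bracket[1])) if tol is None else tol
    lo, hi = float(bracket[0]), float(bracket[1])
    orig_lo, orig_hi = lo, hi
    n_lo = _count(params, control, lo, frozen_value)
    n_hi = _count(params, control, hi, frozen_value)
    if n_lo == n_hi:
        raise FoldBracketError(
            f"no change in equilibrium count over [{lo:g}, {hi:g}] ({n_lo} at both ends)")
    many = lo if n_lo > n_hi else hi  # side with the merging pair
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _count(params, control, mid, frozen_value) == n_lo:
            lo = mid
        else:
            hi = mid
        many = lo if n_lo > n_hi else hi

    # initial S: midpoint of the closest equilibrium pair on the 3-count side
    c, t = _inputs(control, many, frozen_value)
    eqs = find_equilibria(params, c, t)
    if len(eqs) >= 2:
        ss = np.array([e.S for e in eqs])
        i = int(np.argmin(np.diff(ss)))
        s0 = 0.5 * (ss[i] + ss[i + 1])
    else:  # count changed between grid evaluations; fall back to the single root
        s0 = eqs[0].S

    k = kinetics_for(params)
    scale = max(abs(0.5 * (lo + hi)), hi - lo, 1e-30)

    def tangency(v):
        s, u = v
        cc, tt = _inputs(control, u * scale, frozen_value)
        _, g, gp = _scalar_reduction(k, cc, tt)
        return [g(s), gp(s)]

    with warnings.catch_warnings():
        # fsolve complains when xtol outruns the double root's conditioning;
        # acceptance below is on the tangency residuals, not its status
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = fsolve(tangency, [s0, 0.5 * (lo + hi) / scale], xtol=1e-14)
    s_star, c_star = float(sol[0]), float(sol[1] * scale)
    # The count bisection carries a small bias (merging roots closer than the
    # scan grid are counted as one), so the polished tangency root is the
    # authoritative answer.  Accept it on its residuals -- fsolve's status
    # flag is pessimistic once xtol is below what the double root supports.
    rg, rgp = tangency([s_star, c_star / scale])
    good = (
        abs(rg) < 1e-8 * (k.a2 + k.k2 + k.b2 * max(s_star, 1e-12))
        and abs(rgp) < 1e-6 * k.b2
        and orig_lo - tol <= c_star <= orig_hi + tol
        and s_star >= 0
    )
    if not good:
        c_star, s_star = 0.5 * (lo + hi), float(s0)
    cc, tt = _inputs(control, c_star, frozen_value)
    E_of_S, _, _ = _scalar_reduction(k, cc, tt)
    return FoldPoint(control_value=c_star, E=float(E_of_S(s_star)), S=float(s_star))


def trace_branches(
    params: DimensionalParams | NondimParams,
    control: str,
    frozen_value: float,
    interval: Sequence[float],
    n_grid: int = 600,
) -> BifurcationDiagram:
    """Sweep the control input, link equilibria into branches, locate folds.

    Equilibria at consecutive control values are linked by nearest-neighbor
    continuation in (E, S); every change in equilibrium count between grid
    points is bracketed and handed to :func:`locate_fold`.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if lo < 0 or hi <= lo:
        raise ValueError(f"invalid control interval [{lo}, {hi}]")
    grid = np.linspace(lo, hi, n_grid)
    rows = []
    branches: list[dict] = []  # each: {"id": int, "last": (E, S), "open": bool}
    next_id = 0
    counts = np.empty(n_grid, dtype=int)
    for gi, c in enumerate(grid):
        cc, tt = _inputs(control, c, frozen_value)
        eqs = find_equilibria(params, cc, tt)
        counts[gi] = len(eqs)
        open_b = [b for b in branches if b["open"]]
        used = set()
        for eq in eqs:
            best, best_d = None, np.inf
            for b in open_b:
                if b["id"] in used:
                    continue
                d = abs(eq.S - b["last"][1]) + abs(eq.E - b["last"][0])
                if d < best_d:
                    best, best_d = b, d
            if best is None:
                best = {"id": next_id, "last": None, "open": True}
                next_id += 1
                branches.append(best)
            best["last"] = (eq.E, eq.S)
            used.add(best["id"])
            rows.append((c, eq.E, eq.S, eq.stability, best["id"]))
        for b in open_b:
            if b["id"] not in used:
                b["open"] = False

    folds = []
    for gi in range(n_grid - 1):
        if counts[gi] != counts[gi + 1]:
            folds.append(locate_fold(params, control, frozen_value,
                                     (grid[gi], grid[gi + 1])))
    points = pd.DataFrame(rows, columns=["control", "E", "S", "stability", "branch_id"])
    frame = kinetics_for(params).frame
    return BifurcationDiagram(control=control, frozen_value=frozen_value,
                              frame=frame, points=points, folds=tuple(folds))


def classify_switch(
    diagram: BifurcationDiagram,
    admissible_interval: Sequence[float] | None = None,
) -> SwitchClassification:
    """Classify the hysteresis of a traced sweep.

    No folds: no switch.  Two folds inside the admissible interval: a
    reversible switch (both transitions attainable).  One fold: the forward
    transition exists but the return fold lies outside the admissible range
    (e.g. would require negative TGF-beta) -- an irreversible switch.
    """
    if admissible_interval is None:
        lo = float(diagram.points["control"].min())
        hi = float(diagram.points["control"].max())
    else:
        lo, hi = map(float, admissible_interval)
    inside = sorted(f.control_value for f in diagram.folds
                    if lo <= f.control_value <= hi)
    if len(inside) == 0:
        return SwitchClassification(kind="none", thresholds=())
    if len(inside) >= 2:
        return SwitchClassification(kind="reversible", thresholds=tuple(inside))
    return SwitchClassification(kind="irreversible", thresholds=tuple(inside))
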