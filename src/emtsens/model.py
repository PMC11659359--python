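"""Bistable E-cadherin/Slug model of the epithelial-mesenchymal transition.

The dimensional model is a two-variable ODE for membrane-bound E-cadherin
``E`` and the transcription factor Slug ``S``::

    dE/dt = alpha1 / (1 + (S/IC_S)^n1) + k0 * H(C/IC_C; n2) - beta1 * E
    dS/dt = alpha2 - k1 * H(E/IC_E; n3) + k2 * H(T/IC_T; n4) - beta2 * S

where ``H(x; n) = x^n / (1 + x^n)`` is a Hill factor, ``C`` is the neighbor
count (cell-cell contact) and ``T`` the exogenous TGF-beta concentration.
Rescaling states by the half-maximal constants and time by any of seven
characteristic time scales ``gamma`` yields a dimensionless model with seven
grouped parameters ``A1, K0, B1, A2, K1, K2, B2``, one of which (the grouping
that equals ``gamma``) is identically 1.

This module defines the parameter containers for both frames, the right-hand
sides, the seven nondimensionalization schemes, and construction of the
+/-10% sampling ranges used by the sensitivity study.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "HILL_COEFFS",
    "DIMENSIONAL_NAMES",
    "NONDIM_NAMES",
    "GAMMA_PARAMETER",
    "ModelState",
    "DimensionalParams",
    "NondimParams",
    "NondimScheme",
    "ParamRange",
    "TreatmentGroup",
    "hill",
    "rhs_dimensional",
    "rhs_nondimensional",
    "nondimensionalize",
    "gamma_value",
    "grouping_symbols",
    "build_ranges",
]

#: Fixed Hill coefficients (n1, n2, n3, n4); never sampled.
HILL_COEFFS = (3, 4, 2, 3)

#: The 11 sampled dimensional parameters, in canonical column order.
DIMENSIONAL_NAMES = (
    "alpha1", "alpha2", "beta1", "beta2", "k0", "k1", "k2",
    "IC_S", "IC_E", "IC_T", "IC_C",
)

#: The seven grouped dimensionless parameters, in canonical column order.
NONDIM_NAMES = ("A1", "K0", "B1", "A2", "K1", "K2", "B2")

#: For each scheme, the grouping that coincides with gamma and is held at 1.00.
GAMMA_PARAMETER = {1: "A1", 2: "K0", 3: "B1", 4: "A2", 5: "K1", 6: "K2", 7: "B2"}

#: Human-readable definition of gamma for each scheme.
GAMMA_DEFINITION = {
    1: "IC_E / alpha1",
    2: "IC_E / k0",
    3: "1 / beta1",
    4: "IC_S / alpha2",
    5: "IC_S / k1",
    6: "IC_S / k2",
    7: "1 / beta2",
}


class ModelState(NamedTuple):
    """State of the switch: (E, S) concentrations, optionally with time."""

    E: float
    S: float
    t: float = 0.0


def hill(x, n):
    """Saturating Hill factor ``x**n / (1 + x**n)`` for ``x >= 0``.

    Defined as 0 at ``x = 0`` (no 0/0 ambiguity since ``n >= 1``) and
    evaluated as ``1 / (1 + x**-n)`` for ``x > 1`` so large arguments
    saturate to 1 without overflow.  Always lies in ``[0, 1)``.
    """
    scalar = np.isscalar(x) or getattr(x, "ndim", 0) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x < 0):
        raise ValueError("Hill factor argument must be nonnegative")
    small = x <= 1.0
    out = np.empty_like(x)
    xn = x[small] ** n
    out[small] = xn / (1.0 + xn)
    out[~small] = 1.0 / (1.0 + x[~small] ** (-n))
    return float(out[0]) if scalar else out


def _hraw(x: float, n: int) -> float:
    """Hill factor by the raw formula; tolerates small negative arguments.

    Integrators may probe slightly negative states; with integer ``n`` the
    polynomial form stays defined there (odd powers keep their sign).
    """
    xn = x ** n
    return xn / (1.0 + xn)


def _require_positive(obj, names: Iterable[str]) -> None:
    for name in names:
        v = getattr(obj, name)
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{type(obj).__name__}.{name} must be strictly positive and finite, got {v!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """The 11 varied rates/half-maximal constants plus 4 fixed Hill coefficients.

    Units: productions and the ``k`` rates in ng/(mL*min), degradations in
    1/min, half-maximal concentrations in ng/mL, ``IC_C`` in cells.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    k0: float
    k1: float
    k2: float
    IC_S: float
    IC_E: float
    IC_T: float
    IC_C: float
    n1: int = HILL_COEFFS[0]
    n2: int = HILL_COEFFS[1]
    n3: int = HILL_COEFFS[2]
    n4: int = HILL_COEFFS[3]

    def __post_init__(self):
        _require_positive(self, DIMENSIONAL_NAMES)
        for n in ("n1", "n2", "n3", "n4"):
            v = getattr(self, n)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"Hill coefficient {n} must be a positive integer, got {v!r}")

    @property
    def frame(self) -> str:
        return "dimensional"

    def values(self) -> dict:
        return {name: getattr(self, name) for name in DIMENSIONAL_NAMES}

    def replace(self, **kw) -> "DimensionalParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class NondimParams:
    """The seven grouped dimensionless parameters of the rescaled model.

    ``set_id`` records which nondimensionalization scheme produced the
    grouping; the gamma-defining grouping for that scheme is 1.00 at the
    baseline and is never sampled.
    """

    A1: float
    K0: float
    B1: float
    A2: float
    K1: float
    K2: float
    B2: float
    set_id: int = 0
    n1: int = HILL_COEFFS[0]
    n2: int = HILL_COEFFS[1]
    n3: int = HILL_COEFFS[2]
    n4: int = HILL_COEFFS[3]

    def __post_init__(self):
        _require_positive(self, NONDIM_NAMES)
        if self.set_id not in (0, 1, 2, 3, 4, 5, 6, 7):
            raise ValueError(f"set_id must be 0 (unspecified) or 1..7, got {self.set_id!r}")

    @property
    def frame(self) -> str:
        return "nondimensional"

    def values(self) -> dict:
        return {name: getattr(self, name) for name in NONDIM_NAMES}

    def replace(self, **kw) -> "NondimParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class NondimScheme:
    """One of the seven choices of the characteristic time scale gamma."""

    set_id: int

    def __post_init__(self):
        if self.set_id not in GAMMA_PARAMETER:
            raise ValueError(f"set_id must be in 1..7, got {self.set_id!r}")

    @property
    def gamma_definition(self) -> str:
        return GAMMA_DEFINITION[self.set_id]

    @property
    def fixed_parameter(self) -> str:
        """The grouped parameter that equals gamma's grouping, held at 1.00."""
        return GAMMA_PARAMETER[self.set_id]


@dataclass(frozen=True)
class TreatmentGroup:
    """One experimental condition: a (contact, TGF-beta) pair with its start state.

    ``contact``/``tgfb`` are the neighbor count ``C`` (cells) and TGF-beta
    level ``T`` (ng/mL) in the dimensional frame, or ``mu``/``theta`` in a
    nondimensional frame.  ``initial_state`` is the prescribed (E, S) or
    (e, s) starting point.
    """

    contact: float
    tgfb: float
    initial_state: tuple
    frame: str = "dimensional"

    def __post_init__(self):
        if self.contact < 0 or self.tgfb < 0:
            raise ValueError("contact and tgfb levels must be nonnegative")
        if len(self.initial_state) != 2 or any(v < 0 for v in self.initial_state):
            raise ValueError("initial_state must be a nonnegative (E, S) pair")

    @property
    def label(self) -> str:
        if self.frame == "dimensional":
            return f"C={self.contact:g},T={self.tgfb:g}"
        return f"mu={self.contact:g},theta={self.tgfb:g}"


@dataclass(frozen=True)
class ParamRange:
    """Sampling range of one parameter; ``varied=False`` marks a held constant."""

    name: str
    lo: float
    hi: float
    varied: bool = True
    units: str = ""
    frame: str = "dimensional"
    set_id: int | None = None

    def __post_init__(self):
        if self.varied and not (self.lo < self.hi):
            raise ValueError(f"range for {self.name} must have lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _check_inputs(state, contact: float, tgfb: float) -> tuple:
    E, S = float(state[0]), float(state[1])
    if not (math.isfinite(E) and math.isfinite(S)):
        raise ValueError(f"nonfinite state ({E}, {S})")
    if contact < 0:
        raise ValueError(f"contact must be nonnegative, got {contact}")
    if tgfb < 0:
        raise ValueError(f"TGF-beta level must be nonnegative, got {tgfb}")
    return E, S


def rhs_dimensional(state, params: DimensionalParams, C: float, T: float) -> np.ndarray:
    """Time derivatives (dE/dt, dS/dt) of the dimensional model."""
    E, S = _check_inputs(state, C, T)
    p = params
    dE = (
        p.alpha1 / (1.0 + (S / p.IC_S) ** p.n1)
        + p.k0 * hill(C / p.IC_C, p.n2)
        - p.beta1 * E
    )
    dS = (
        p.alpha2
        - p.k1 * _hraw(E / p.IC_E, p.n3)
        + p.k2 * hill(T / p.IC_T, p.n4)
        - p.beta2 * S
    )
    return np.array([dE, dS])


def rhs_nondimensional(state, params: NondimParams, mu: float, theta: float) -> np.ndarray:
    """Time derivatives (de/dtau, ds/dtau) of the rescaled model."""
    e, s = _check_inputs(state, mu, theta)
    p = params
    de = p.A1 / (1.0 + s ** p.n1) + p.K0 * hill(mu, p.n2) - p.B1 * e
    ds = p.A2 - p.K1 * _hraw(e, p.n3) + p.K2 * hill(theta, p.n4) - p.B2 * s
    return np.array([de, ds])


def gamma_value(params: DimensionalParams, scheme: NondimScheme | int) -> float:
    """The characteristic time scale gamma (minutes) for a scheme."""
    set_id = scheme.set_id if isinstance(scheme, NondimScheme) else int(scheme)
    p = params
    return {
        1: p.IC_E / p.alpha1,
        2: p.IC_E / p.k0,
        3: 1.0 / p.beta1,
        4: p.IC_S / p.alpha2,
        5: p.IC_S / p.k1,
        6: p.IC_S / p.k2,
        7: 1.0 / p.beta2,
    }[set_id]


def nondimensionalize(params: DimensionalParams, scheme: NondimScheme | int) -> NondimParams:
    """Group the dimensional parameters under one of the seven schemes.

    With states rescaled by (IC_E, IC_S), inputs by (IC_C, IC_T) and time by
    gamma, the groupings are ``A1 = alpha1*gamma/IC_E``, ``K0 = k0*gamma/IC_E``,
    ``B1 = beta1*gamma``, ``A2 = alpha2*gamma/IC_S``, ``K1 = k1*gamma/IC_S``,
    ``K2 = k2*gamma/IC_S`` and ``B2 = beta2*gamma``.  The grouping matching
    gamma's definition cancels to exactly 1.
    """
    set_id = scheme.set_id if isinstance(scheme, NondimScheme) else int(scheme)
    if set_id not in GAMMA_PARAMETER:
        raise ValueError(f"set_id must be in 1..7, got {set_id!r}")
    g = gamma_value(params, set_id)
    p = params
    values = {
        "A1": p.alpha1 * g / p.IC_E,
        "K0": p.k0 * g / p.IC_E,
        "B1": p.beta1 * g,
        "A2": p.alpha2 * g / p.IC_S,
        "K1": p.k1 * g / p.IC_S,
        "K2": p.k2 * g / p.IC_S,
        "B2": p.beta2 * g,
    }
    values[GAMMA_PARAMETER[set_id]] = 1.0  # exact self-cancellation
    return NondimParams(set_id=set_id, n1=p.n1, n2=p.n2, n3=p.n3, n4=p.n4, **values)


def grouping_symbols(set_id: int) -> dict[str, frozenset[str]]:
    """Dimensional parameters entering each grouped parameter, derived symbolically.

    Builds the grouping formulas ``A1 = alpha1*gamma/IC_E`` etc. with sympy,
    substitutes the scheme's gamma, simplifies, and reads off the surviving
    free symbols.  The gamma-defining grouping cancels to 1 (empty set).
    """
    import sympy as sp

    syms = {name: sp.Symbol(name, positive=True) for name in DIMENSIONAL_NAMES}
    s = syms
    gamma = {
        1: s["IC_E"] / s["alpha1"],
        2: s["IC_E"] / s["k0"],
        3: 1 / s["beta1"],
        4: s["IC_S"] / s["alpha2"],
        5: s["IC_S"] / s["k1"],
        6: s["IC_S"] / s["k2"],
        7: 1 / s["beta2"],
    }[set_id]
    formulas = {
        "A1": s["alpha1"] * gamma / s["IC_E"],
        "K0": s["k0"] * gamma / s["IC_E"],
        "B1": s["beta1"] * gamma,
        "A2": s["alpha2"] * gamma / s["IC_S"],
        "K1": s["k1"] * gamma / s["IC_S"],
        "K2": s["k2"] * gamma / s["IC_S"],
        "B2": s["beta2"] * gamma,
    }
    return {
        name: frozenset(str(f) for f in sp.simplify(expr).free_symbols)
        for name, expr in formulas.items()
    }


def build_ranges(
    center_values: Mapping[str, float],
    overrides: Mapping[str, Sequence[float]] | None = None,
    fraction: float = 0.10,
    fixed: Iterable[str] = (),
    decimals: int | None = 4,
    frame: str = "dimensional",
    set_id: int | None = None,
    units: Mapping[str, str] | None = None,
) -> list[ParamRange]:
    """Construct per-parameter sampling ranges ``[(1-f)*v, (1+f)*v]``.

    ``overrides`` supplies ranges that were shifted off-center (the overall
    width, ``2*fraction*center``, is preserved in the published design; an
    override whose width deviates by more than rounding tolerance triggers a
    warning but is kept verbatim).  Names in ``fixed`` (the gamma grouping of
    a nondimensional set) get ``varied=False`` with lo = hi = center.
    Endpoints are rounded to ``decimals`` places to match the printed tables.
    """
    overrides = dict(overrides or {})
    fixed = set(fixed)
    units = units or {}
    out = []
    for name, center in center_values.items():
        if name in fixed:
            out.append(ParamRange(name, center, center, varied=False,
                                  units=units.get(name, ""), frame=frame, set_id=set_id))
            continue
        if name in overrides:
            lo, hi = map(float, overrides[name])
            expected = 2.0 * fraction * center
            # printed endpoints carry rounding at the table's precision
            tol = max(2e-4 * center, 2 * 10.0 ** -(decimals or 12))
            if abs((hi - lo) - expected) > tol:
                warnings.warn(
                    f"override for {name}: width {hi - lo:g} differs from "
                    f"{2 * fraction:.0%} of center ({expected:g})",
                    stacklevel=2,
                )
        else:
            lo, hi = (1.0 - fraction) * center, (1.0 + fraction) * center
            if decimals is not None:
                # published endpoints carry `decimals` places in the value's
                # printed decade (e.g. 3.2760e-6 for a 1e-6-scale constant)
                scale = 10.0 ** math.floor(math.log10(center)) if center < 1e-3 else 1.0
                lo = round(lo / scale, decimals) * scale
                hi = round(hi / scale, decimals) * scale
        out.append(ParamRange(name, lo, hi, varied=True,
                              units=units.get(name, ""), frame=frame, set_id=set_id))
    return out
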