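"""Time integration to steady state and algebraic equilibrium analysis.

The study's readout rule is "state at t = 10000, rounded" (1e-4 in the
dimensional frame, 1e-2 in the nondimensional frames; rounding makes the
parameter-to-output maps monotone by quantizing away solver-level noise).
Integration uses LSODA with an analytic Jacobian at rtol 1e-10 / atol 1e-12:
dimensional state magnitudes reach 1e-4, so looser tolerances would corrupt
the 4-decimal rounding.

Equilibria are found by reducing the two nullcline equations to a single
scalar residual in S: at equilibrium E is an explicit function of S from the
E-equation, which substituted into the S-equation gives g(S); all roots are
bracketed on a bounded S-grid and polished.  Stability comes from the
trace/determinant of the analytic 2x2 Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import brentq

from .model import DimensionalParams, NondimParams, TreatmentGroup, hill

__all__ = [
    "ROUNDING_GRAIN",
    "SteadyStateResult",
    "Equilibrium",
    "Kinetics",
    "kinetics_for",
    "round_output",
    "integrate_to_steady_state",
    "steady_state_outputs",
    "find_equilibria",
    "IntegrationError",
    "EquilibriumBoundsError",
]

#: Output rounding grain per frame.
ROUNDING_GRAIN = {"dimensional": 1e-4, "nondimensional": 1e-2}

#: Convergence tolerance on max |rhs| for the `converged` diagnostic flag.
CONVERGENCE_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Solver failure or nonfinite state; carries the offending parameters."""

    def __init__(self, message, params=None, group=None):
        super().__init__(message)
        self.params = params
        self.group = group


class EquilibriumBoundsError(RuntimeError):
    """The equilibrium scan grid clips a root; widen the bounds."""


@dataclass(frozen=True)
class Kinetics:
    """Frame-agnostic kinetic coefficients of the switch model.

    Both frames share the structure::

        dE/dt = a1 / (1 + (S/s_scale)^n1) + k0 * H(C/c_scale; n2) - b1 * E
        dS/dt = a2 - k1 * H(E/e_scale; n3) + k2 * H(T/t_scale; n4) - b2 * S

    with all four scales equal to 1 in the nondimensional frames.
    """

    a1: float
    k0: float
    b1: float
    a2: float
    k1: float
    k2: float
    b2: float
    e_scale: float
    s_scale: float
    c_scale: float
    t_scale: float
    n1: int
    n2: int
    n3: int
    n4: int
    frame: str


def kinetics_for(params: DimensionalParams | NondimParams) -> Kinetics:
    if isinstance(params, DimensionalParams):
        return Kinetics(params.alpha1, params.k0, params.beta1, params.alpha2,
                        params.k1, params.k2, params.beta2,
                        params.IC_E, params.IC_S, params.IC_C, params.IC_T,
                        params.n1, params.n2, params.n3, params.n4, "dimensional")
    if isinstance(params, NondimParams):
        return Kinetics(params.A1, params.K0, params.B1, params.A2,
                        params.K1, params.K2, params.B2,
                        1.0, 1.0, 1.0, 1.0,
                        params.n1, params.n2, params.n3, params.n4, "nondimensional")
    raise TypeError(f"unsupported parameter object {type(params).__name__}")


def _frame_key(frame: str) -> str:
    return "dimensional" if frame == "dimensional" else "nondimensional"


def round_output(value: float, frame: str) -> float:
    """Round to the frame's grain, half away from zero.

    Dimensional outputs are rounded to the nearest 1e-4, nondimensional to
    the nearest 1e-2.  numpy/banker's rounding would send exact halves to the
    even neighbor; the half-away-from-zero convention is used instead so the
    tie 0.00005 -> 0.0001.
    """
    if not np.isfinite(value):
        raise ValueError(f"cannot round nonfinite value {value!r}")
    grain = ROUNDING_GRAIN[_frame_key(frame)]
    q = np.floor(np.abs(value) / grain + 0.5)
    return float(np.sign(value) * q * grain)


@dataclass(frozen=True)
class SteadyStateResult:
    """State at the readout time with the study's rounding applied."""

    E_ss: float
    S_ss: float
    rounded_E: float
    rounded_S: float
    converged: bool
    negative_excursion: bool


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its linear stability type."""

    E: float
    S: float
    stability: str  # "stable" | "saddle" | "unstable"


def _rhs_and_jac(k: Kinetics, contact: float, tgfb: float):
    """Closures for the rhs and analytic Jacobian with constant inputs folded in."""
    drive_E = k.k0 * hill(contact / k.c_scale, k.n2)
    drive_S = k.a2 + k.k2 * hill(tgfb / k.t_scale, k.n4)
    a1, b1, k1, b2 = k.a1, k.b1, k.k1, k.b2
    sS, sE, n1, n3 = k.s_scale, k.e_scale, k.n1, k.n3

    def rhs(y, t=0.0):
        E, S = y
        hs = (S / sS) ** n1
        ze = (E / sE) ** n3
        return (
            a1 / (1.0 + hs) + drive_E - b1 * E,
            drive_S - k1 * ze / (1.0 + ze) - b2 * S,
        )

    def jac(y, t=0.0):
        E, S = y
        x = S / sS
        z = E / sE
        dE_dS = -a1 * n1 * x ** (n1 - 1) / sS / (1.0 + x ** n1) ** 2
        dS_dE = -k1 * n3 * z ** (n3 - 1) / sE / (1.0 + z ** n3) ** 2
        return ((-b1, dE_dS), (dS_dE, -b2))

    return rhs, jac


def integrate_to_steady_state(
    group: TreatmentGroup,
    params: DimensionalParams | NondimParams,
    t_end: float = 10000.0,
    check_negative: bool = True,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SteadyStateResult:
    """Integrate from the group's initial condition and read out at ``t_end``.

    The readout is strictly the state at ``t_end`` (no early exit); the
    ``converged`` flag records whether max |rhs| < 1e-9 there.  When
    ``check_negative`` is set the trajectory is sampled on a geometric time
    grid and any component below -1e-9 flags ``negative_excursion`` (flagged,
    not fatal: the published ranges were shifted to avoid this regime).
    """
    k = kinetics_for(params)
    rhs, jac = _rhs_and_jac(k, group.contact, group.tgfb)
    if check_negative:
        ts = np.concatenate([[0.0], np.geomspace(max(t_end * 1e-5, 1e-3), t_end, 48)])
    else:
        ts = np.array([0.0, t_end])
    y, info = odeint(rhs, group.initial_state, ts, Dfun=jac,
                     rtol=rtol, atol=atol, full_output=True, mxstep=100000)
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        raise IntegrationError(f"integration failed for {group.label}: {info['message']}",
                               params=params, group=group)
    E, S = float(y[-1, 0]), float(y[-1, 1])
    resid = rhs((E, S))
    frame = k.frame
    return SteadyStateResult(
        E_ss=E,
        S_ss=S,
        rounded_E=round_output(E, frame),
        rounded_S=round_output(S, frame),
        converged=bool(max(abs(resid[0]), abs(resid[1])) < CONVERGENCE_TOL),
        negative_excursion=bool(np.any(y < -1e-9)),
    )


def steady_state_outputs(
    params_seq: Sequence[DimensionalParams | NondimParams],
    group: TreatmentGroup,
    t_end: float = 10000.0,
) -> np.ndarray:
    """Rounded (E, S) readouts for a sequence of parameter sets under one group.

    Fast path for the sampling study: skips the negative-excursion time grid
    and the per-call container overhead of :func:`integrate_to_steady_state`.
    Returns an (n, 2) array of rounded outputs.
    """
    out = np.empty((len(params_seq), 2))
    y0 = group.initial_state
    ts = np.array([0.0, t_end])
    for i, params in enumerate(params_seq):
        k = kinetics_for(params)
        rhs, jac = _rhs_and_jac(k, group.contact, group.tgfb)
        y = odeint(rhs, y0, ts, Dfun=jac, rtol=1e-10, atol=1e-12, mxstep=100000)
        if not np.all(np.isfinite(y[-1])):
            raise IntegrationError(f"nonfinite state in sample {i} of {group.label}",
                                   params=params, group=group)
        out[i, 0] = round_output(float(y[-1, 0]), k.frame)
        out[i, 1] = round_output(float(y[-1, 1]), k.frame)
    return out


def _scalar_reduction(k: Kinetics, contact: float, tgfb: float):
    """Reduce the equilibrium system to one scalar equation in S.

    Returns ``(E_of_S, g, g_prime)`` where ``g(S) = dS/dt`` evaluated on the
    E-nullcline ``E = E_of_S(S)`` and ``g_prime`` is its analytic derivative.
    """
    drive_E = k.k0 * hill(contact / k.c_scale, k.n2)
    drive_S = k.a2 + k.k2 * hill(tgfb / k.t_scale, k.n4)
    a1, b1, k1, b2 = k.a1, k.b1, k.k1, k.b2
    sS, sE, n1, n3 = k.s_scale, k.e_scale, k.n1, k.n3

    def E_of_S(S):
        return (a1 / (1.0 + (S / sS) ** n1) + drive_E) / b1

    def g(S):
        z = E_of_S(S) / sE
        zn = z ** n3
        return drive_S - k1 * zn / (1.0 + zn) - b2 * S

    def g_prime(S):
        x = S / sS
        Ep = -(a1 * n1 * x ** (n1 - 1) / sS) / (1.0 + x ** n1) ** 2 / b1
        z = E_of_S(S) / sE
        dh = n3 * z ** (n3 - 1) / sE / (1.0 + z ** n3) ** 2
        return -k1 * dh * Ep - b2

    return E_of_S, g, g_prime


def _classify(k: Kinetics, E: float, S: float, contact: float, tgfb: float) -> str:
    _, jac = _rhs_and_jac(k, contact, tgfb)
    (j11, j12), (j21, j22) = jac((E, S))
    tr = j11 + j22
    det = j11 * j22 - j12 * j21
    if det < 0:
        return "saddle"
    return "stable" if tr < 0 else "unstable"


def find_equilibria(
    params: DimensionalParams | NondimParams,
    contact: float,
    tgfb: float,
    n_grid: int = 2000,
) -> list[Equilibrium]:
    """All fixed points for given inputs, with stability, ordered by S.

    Scans ``S`` on [0, 2*(a2+k2)/b2] (an upper bound exceeding any attainable
    steady-state S, since dS/dt <= a2 + k2 - b2*S), brackets every sign change
    of the scalar residual and polishes each root to ~1e-14.
    """
    if contact < 0 or tgfb < 0:
        raise ValueError("contact and tgfb must be nonnegative")
    k = kinetics_for(params)
    E_of_S, g, _ = _scalar_reduction(k, contact, tgfb)
    s_max = 2.0 * (k.a2 + k.k2) / k.b2
    grid = np.linspace(0.0, s_max, n_grid)
    vals = g(grid)  # residual closure is numpy-vectorized
    if vals[-1] >= 0:
        raise EquilibriumBoundsError(
            f"residual nonnegative at S={s_max:g}; widen the scan bounds")
    roots = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16))
    return [Equilibrium(E=float(E_of_S(s)), S=float(s),
                        stability=_classify(k, float(E_of_S(s)), float(s), contact, tgfb))
            for s in roots]
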