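"""Packaged default configuration: tabulated parameter values, sampling ranges,
treatment levels and initial conditions for the dimensional model and the
seven nondimensional sets.

All quantities live in ``data/defaults.yaml`` (one documented key per table
entry).  Ranges are stored verbatim as published; :func:`range_consistency`
regenerates them from the centers and reports any cell that disagrees beyond
printing precision (the Set 1 ``K0`` entry is a known inconsistency: the
published grouped value 0.646 differs from the computed ``k0/alpha1`` =
0.6432, and the published range was built from the former).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import yaml

from .model import (
    DIMENSIONAL_NAMES,
    GAMMA_PARAMETER,
    NONDIM_NAMES,
    DimensionalParams,
    NondimParams,
    ParamRange,
    TreatmentGroup,
    build_ranges,
    nondimensionalize,
)

__all__ = [
    "load_defaults",
    "default_dimensional_params",
    "default_nondim_params",
    "dimensional_ranges",
    "nondim_ranges",
    "ranges_for_frame",
    "baseline_for_frame",
    "treatment_groups",
    "study_defaults",
    "range_consistency",
    "ranges_to_csv",
    "FRAMES",
]

#: All model frames of the study, in canonical order.
FRAMES = ("dimensional",) + tuple(f"set{k}" for k in range(1, 8))


@lru_cache(maxsize=1)
def load_defaults() -> dict:
    """Parsed contents of the packaged ``defaults.yaml``."""
    ref = importlib.resources.files("emtsens.data").joinpath("defaults.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _set_id(frame: str) -> int:
    if not (frame.startswith("set") and frame[3:].isdigit()):
        raise ValueError(f"unknown nondimensional frame {frame!r}")
    k = int(frame[3:])
    if k not in GAMMA_PARAMETER:
        raise ValueError(f"set id must be 1..7, got {k}")
    return k


def default_dimensional_params(config: Mapping | None = None) -> DimensionalParams:
    cfg = config or load_defaults()
    values = {k: v["value"] for k, v in cfg["dimensional"]["parameters"].items()}
    hillc = cfg["dimensional"]["hill"]
    return DimensionalParams(**values, **hillc)


def default_nondim_params(frame: str | int, config: Mapping | None = None) -> NondimParams:
    """Baseline grouped parameters for ``set1``..``set7`` (regenerated, not stored)."""
    set_id = frame if isinstance(frame, int) else _set_id(frame)
    return nondimensionalize(default_dimensional_params(config), set_id)


def dimensional_ranges(config: Mapping | None = None) -> list[ParamRange]:
    """The 11 published dimensional sampling ranges (verbatim)."""
    cfg = config or load_defaults()
    units = {k: v["units"] for k, v in cfg["dimensional"]["parameters"].items()}
    out = []
    for name in DIMENSIONAL_NAMES:
        lo, hi = cfg["dimensional"]["ranges"][name]
        out.append(ParamRange(name, float(lo), float(hi), varied=True,
                              units=units[name], frame="dimensional"))
    return out


def nondim_ranges(frame: str | int, config: Mapping | None = None) -> list[ParamRange]:
    """Published grouped-parameter ranges for one set (verbatim).

    The gamma-defining grouping is returned with ``varied=False`` at 1.00.
    """
    set_id = frame if isinstance(frame, int) else _set_id(frame)
    cfg = config or load_defaults()
    table = cfg["nondimensional"]["ranges"][f"set{set_id}"]
    out = []
    for name in NONDIM_NAMES:
        entry = table[name]
        if entry is None:
            out.append(ParamRange(name, 1.0, 1.0, varied=False, units="-",
                                  frame=f"set{set_id}", set_id=set_id))
        else:
            lo, hi = map(float, entry)
            out.append(ParamRange(name, lo, hi, varied=True, units="-",
                                  frame=f"set{set_id}", set_id=set_id))
    return out


def ranges_for_frame(frame: str, config: Mapping | None = None) -> list[ParamRange]:
    if frame == "dimensional":
        return dimensional_ranges(config)
    return nondim_ranges(frame, config)


def baseline_for_frame(frame: str, config: Mapping | None = None):
    if frame == "dimensional":
        return default_dimensional_params(config)
    return default_nondim_params(frame, config)


def treatment_groups(frame: str = "dimensional", config: Mapping | None = None) -> list[TreatmentGroup]:
    """The 8 treatment groups (contact x TGF-beta cross) for a frame.

    Initial conditions are keyed by contact level and shared across the two
    TGF-beta levels; all seven nondimensional sets share the same rescaled
    initial conditions and input levels.
    """
    cfg = config or load_defaults()
    section = cfg["dimensional"] if frame == "dimensional" else cfg["nondimensional"]
    tr = section["treatments"]
    groups = []
    for t in tr["tgfb_levels"]:
        for c in tr["contact_levels"]:
            ic = tr["initial_conditions"][f"{float(c):g}"]
            groups.append(TreatmentGroup(contact=float(c), tgfb=float(t),
                                         initial_state=(float(ic[0]), float(ic[1])),
                                         frame=frame))
    return groups


def study_defaults(config: Mapping | None = None) -> dict:
    cfg = config or load_defaults()
    return dict(cfg["study"])


@dataclass(frozen=True)
class RangeDiscrepancy:
    """A stored range endpoint that the regenerated value does not reproduce."""

    frame: str
    name: str
    stored: tuple
    regenerated: tuple
    max_abs_error: float


def range_consistency(tol: float = 1.5e-4, config: Mapping | None = None) -> list[RangeDiscrepancy]:
    """Regenerate every non-shifted range from its center and diff the tables.

    Dimensional centers are the Table-of-parameters values; nondimensional
    centers are the grouped values rounded to the 3 decimals at which they
    were published (the published ranges were built from the rounded
    centers).  Shifted parameters (alpha2/k1 and A2/K1) are stored as data --
    no formula reproduces the shift -- and are skipped.  Returns the list of
    disagreeing cells; with the packaged tables this flags exactly the
    Set 1 ``K0`` inconsistency.
    """
    cfg = config or load_defaults()
    issues: list[RangeDiscrepancy] = []

    dim = default_dimensional_params(cfg)
    shifted = set(cfg["dimensional"]["shifted"])
    regen = {
        r.name: r
        for r in build_ranges(dim.values(), fraction=0.10, decimals=4, frame="dimensional")
    }
    for r in dimensional_ranges(cfg):
        if r.name in shifted:
            continue
        g = regen[r.name]
        # IC_T is printed in units of 1e-6; compare at matching precision
        scale = 1e-6 if r.name == "IC_T" else 1.0
        err = max(abs(r.lo - g.lo), abs(r.hi - g.hi)) / scale
        if err > tol:
            issues.append(RangeDiscrepancy("dimensional", r.name, (r.lo, r.hi), (g.lo, g.hi), err))

    shifted_nd = set(cfg["nondimensional"]["shifted"])
    for set_id in range(1, 8):
        params = default_nondim_params(set_id, cfg)
        centers = {k: round(v, 3) for k, v in params.values().items()}
        regen = {
            r.name: r
            for r in build_ranges(centers, fraction=0.10,
                                  fixed={GAMMA_PARAMETER[set_id]}, decimals=4,
                                  frame=f"set{set_id}", set_id=set_id)
        }
        for r in nondim_ranges(set_id, cfg):
            if not r.varied or r.name in shifted_nd:
                continue
            g = regen[r.name]
            err = max(abs(r.lo - g.lo), abs(r.hi - g.hi))
            if err > tol:
                issues.append(RangeDiscrepancy(f"set{set_id}", r.name, (r.lo, r.hi), (g.lo, g.hi), err))
    return issues


def ranges_to_csv(ranges: list[ParamRange], path, values: Mapping[str, float] | None = None) -> None:
    """Export a range table with columns (name, value, lo, hi, varied, units, frame, set_id)."""
    values = values or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "value", "lo", "hi", "varied", "units", "frame", "set_id"])
        for r in ranges:
            w.writerow([r.name, values.get(r.name, ""), r.lo, r.hi,
                        int(r.varied), r.units, r.frame, "" if r.set_id is None else r.set_id])
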