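"""Latin Hypercube Sampling of parameter space -- the study's input generator.

Each varied parameter's interval is split into N equal-width strata and one
point is drawn per stratum (uniformly within it, or at the midpoint in
deterministic mode); the stratum order is then permuted independently per
column, so every column is exactly stratified and columns are independent.

Per-column random streams are derived from one global seed keyed by the
parameter *name* (CRC-32 of the name spawns the column's SeedSequence), so
adding or removing a column never perturbs the draws of the others, and the
same (seed, name) pair yields the same unit-interval draws in every frame --
the frame comparison of the full study is therefore not confounded by
sampling noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DimensionalParams, NondimParams, ParamRange

__all__ = ["SampleMatrix", "latin_hypercube", "assemble_parameter_sets"]


@dataclass(frozen=True)
class SampleMatrix:
    """An N x K Latin hypercube design with per-column range metadata."""

    values: np.ndarray
    ranges: tuple
    seed: int

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> tuple:
        return tuple(r.name for r in self.ranges)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the design as CSV; the seed goes to a JSON sidecar."""
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {"seed": self.seed, "N": self.N,
                    "columns": [{"name": r.name, "lo": r.lo, "hi": r.hi} for r in self.ranges]}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)


def _column_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def latin_hypercube(
    ranges: Sequence[ParamRange],
    N: int,
    seed: int,
    jitter: bool = True,
) -> SampleMatrix:
    """Draw an N-sample Latin hypercube over the varied ranges.

    Enforces the design-size rule N > (4/3) K (so K = 11 requires N >= 15 and
    K = 6 requires N >= 9).  With ``jitter=False`` each stratum contributes
    its midpoint (deterministic up to the permutation).
    """
    varied = [r for r in ranges if r.varied]
    K = len(varied)
    if K == 0:
        raise ValueError("no varied ranges to sample")
    for r in varied:
        if not (r.lo < r.hi):
            raise ValueError(f"degenerate range for {r.name}: [{r.lo}, {r.hi}]")
    if N < 2:
        raise ValueError(f"need at least 2 samples, got {N}")
    if N <= 4.0 * K / 3.0:
        raise ValueError(f"LHS design too small: N={N} must exceed 4K/3 = {4 * K / 3:.2f} for K={K}")
    values = np.empty((N, K))
    strata = np.arange(N, dtype=float)
    for j, r in enumerate(varied):
        rng = _column_rng(seed, r.name)
        perm = rng.permutation(N)
        offset = rng.uniform(size=N) if jitter else np.full(N, 0.5)
        unit = (strata + offset) / N
        values[:, j] = r.lo + (r.hi - r.lo) * unit[perm]
    return SampleMatrix(values=values, ranges=tuple(varied), seed=int(seed))


def assemble_parameter_sets(
    matrix: SampleMatrix,
    baseline: DimensionalParams | NondimParams,
) -> list:
    """Turn each design row into a complete parameter object.

    Columns override the matching baseline fields; everything else (fixed
    Hill coefficients, a nondimensional set's gamma grouping held at 1.00)
    keeps its baseline value.  Row order is preserved so PRCC can align
    inputs with outputs.
    """
    names = matrix.names
    for name in names:
        if not hasattr(baseline, name):
            raise ValueError(f"sample column {name!r} has no counterpart in "
                             f"{type(baseline).__name__}")
    out = []
    for row in matrix.values:
        out.append(dc_replace(baseline, **dict(zip(names, row))))
    return out
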