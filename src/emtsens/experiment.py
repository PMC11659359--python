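"""Full-study orchestration: every frame (dimensional + Sets 1-7) x 8 treatment
groups, LHS -> steady-state readouts -> PRCC -> significance grids, and the
dimensional-vs-nondimensional comparison report.

The headline comparison asks two questions.  (1) Do the seven
nondimensionalizations agree with each other on which grouped parameters are
significant?  (They do for Slug in every treatment group, but disagree for
E-cadherin in the bistable contact conditions without TGF-beta.)  (2) Which
dimensional parameters can no nondimensional analysis see at all?  The
half-maximal input constants IC_C and IC_T cancel out of every grouping --
they rescale the inputs themselves -- so their influence is structurally
invisible after nondimensionalization.

By default the same per-column unit-interval draws (keyed by seed and column
name) are reused across frames, so cross-frame differences in the grids are
not confounded by sampling noise; a fully independent per-frame design is
available with ``shared_design=False``.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import config as cfg
from .dynamics import steady_state_outputs
from .model import TreatmentGroup, grouping_symbols
from .prcc import PRCCResult, classify_significance, prcc_all
from .sampling import SampleMatrix, assemble_parameter_sets, latin_hypercube

__all__ = ["StudyConfig", "FrameResult", "ComparisonReport", "StudyResult",
           "run_study", "run_frame", "report_discrepancies"]

logger = logging.getLogger("emtsens")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the full sampling/sensitivity study.

    Defaults reproduce the published design: N = 10000 uniform LHS samples,
    all eight frames, the 8 treatment groups per frame, readout at
    t = 10000 with 1e-4 / 1e-2 rounding, significance cutoff |rho| = 0.5.
    """

    N: int = 10000
    seed: int = 0
    frames: tuple = cfg.FRAMES
    threshold: float = 0.5
    t_end: float = 10000.0
    jitter: bool = True
    shared_design: bool = True

    def __post_init__(self):
        unknown = set(self.frames) - set(cfg.FRAMES)
        if unknown:
            raise ValueError(f"unknown frames {sorted(unknown)}; valid: {cfg.FRAMES}")


@dataclass(frozen=True)
class FrameResult:
    """All per-frame tables: design, rounded outputs, PRCC, significance."""

    frame: str
    matrix: SampleMatrix
    outputs: dict          # group label -> (N, 2) rounded (E, S) readouts
    prcc: dict             # (group label, output name) -> PRCCResult
    table: pd.DataFrame    # rows = parameters, columns = (group, output), cells = rho

    def significance(self) -> dict:
        return {key: classify_significance(res) for key, res in self.prcc.items()}


@dataclass(frozen=True)
class ComparisonReport:
    """Cross-frame significance comparison.

    ``grid``            frame -> (group label, output letter) -> significant set
    ``discrepancies``   (group, output) cells where the seven nondimensional
                        sets disagree among themselves
    ``lost_parameters`` dimensional parameters that were significant somewhere
                        yet appear in no grouped parameter of any set (their
                        influence is invisible to every nondimensional analysis)
    """

    grid: dict
    discrepancies: tuple
    lost_parameters: tuple

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o).__name__)
        payload = {
            "grid": {f: {f"{g}|{o}": sorted(s) for (g, o), s in cells.items()}
                     for f, cells in self.grid.items()},
            "discrepancies": [
                {"group": g, "output": o, "per_frame": {f: sorted(s) for f, s in per.items()}}
                for (g, o, per) in self.discrepancies
            ],
            "lost_parameters": [
                {"parameter": p, "group": g, "output": o}
                for (p, g, o) in self.lost_parameters
            ],
        }
        return json.dumps(payload, indent=1, default=enc)

    def to_text(self) -> str:
        lines = ["Dimensional vs nondimensional significance comparison", ""]
        if not self.discrepancies:
            lines.append("All nondimensional sets agree in every treatment group.")
        for g, o, per in self.discrepancies:
            lines.append(f"Sets disagree at {g}, output {o}:")
            for f, s in sorted(per.items()):
                lines.append(f"  {f}: {{{', '.join(sorted(s))}}}")
        lines.append("")
        if self.lost_parameters:
            lines.append("Dimensional parameters invisible to every nondimensionalization:")
            for p, g, o in self.lost_parameters:
                lines.append(f"  {p} (significant for {o} at {g})")
        return "\n".join(lines)


@dataclass(frozen=True)
class StudyResult:
    config: StudyConfig
    frames: dict            # frame name -> FrameResult
    report: ComparisonReport | None

    def write(self, outdir) -> None:
        """Write per-frame PRCC CSVs, the significance grid and the report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, fr in self.frames.items():
            fr.table.to_csv(outdir / f"prcc_{name}.csv")
        if self.report is not None:
            (outdir / "comparison.json").write_text(self.report.to_json())
            (outdir / "comparison.txt").write_text(self.report.to_text())
        grid_rows = []
        for fname, fr in self.frames.items():
            for (g, o), res in fr.prcc.items():
                grid_rows.append({
                    "frame": fname, "group": g, "output": o,
                    "significant": ";".join(sorted(classify_significance(res))),
                })
        pd.DataFrame(grid_rows).to_csv(outdir / "significance_grid.csv", index=False)


def _frame_seed(seed: int, frame: str, shared: bool) -> int:
    if shared:
        return seed
    ss = np.random.SeedSequence([int(seed), zlib.crc32(frame.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_frame(frame: str, study: StudyConfig) -> FrameResult:
    """LHS -> readouts -> PRCC for one frame across its 8 treatment groups.

    One design is drawn per frame and reused for all treatment groups (one
    LHS design, eight condition evaluations).
    """
    ranges = cfg.ranges_for_frame(frame)
    baseline = cfg.baseline_for_frame(frame)
    groups = cfg.treatment_groups("dimensional" if frame == "dimensional" else "nondimensional")
    matrix = latin_hypercube(ranges, study.N, _frame_seed(study.seed, frame, study.shared_design),
                             jitter=study.jitter)
    param_sets = assemble_parameter_sets(matrix, baseline)
    out_names = ("E", "S") if frame == "dimensional" else ("e", "s")
    outputs, prcc_results, cols = {}, {}, {}
    for group in groups:
        logger.info("frame %s, group %s: integrating %d samples", frame, group.label, study.N)
        ys = steady_state_outputs(param_sets, group, t_end=study.t_end)
        outputs[group.label] = ys
        for oi, oname in enumerate(out_names):
            rho = prcc_all(matrix.values, ys[:, oi], names=matrix.names)
            res = PRCCResult(output_name=oname, group=group, rho=rho,
                             threshold=study.threshold)
            prcc_results[(group.label, oname)] = res
            cols[(group.label, oname)] = rho
    table = pd.DataFrame(cols)
    table.index.name = "parameter"
    return FrameResult(frame=frame, matrix=matrix, outputs=outputs,
                       prcc=prcc_results, table=table)


def _normalize_output(name: str) -> str:
    return name.upper()


def report_discrepancies(grids: Mapping[str, Mapping]) -> ComparisonReport:
    """Build the comparison report from per-frame significance grids.

    ``grids`` maps frame name -> {(group label, output name): set of names}.
    Group cells are aligned across frames by position in the canonical
    treatment order (contact levels cross TGF-beta levels), since dimensional
    and nondimensional frames label their conditions differently.
    """
    frames = list(grids.keys())
    nd_frames = [f for f in frames if f != "dimensional"]
    aligned: dict[str, dict] = {}
    n_cells = None
    for f in frames:
        cells = grids[f]
        ordered = list(cells.items())
        if n_cells is None:
            n_cells = len(ordered)
        elif len(ordered) != n_cells:
            raise ValueError(f"frame {f!r} has {len(ordered)} grid cells, expected {n_cells}")
        aligned[f] = {i: (g, _normalize_output(o), set(s))
                      for i, ((g, o), s) in enumerate(ordered)}

    discrepancies = []
    if nd_frames:
        for i in range(n_cells):
            per = {f: aligned[f][i][2] for f in nd_frames}
            if len({frozenset(s) for s in per.values()}) > 1:
                g, o, _ = aligned[nd_frames[0]][i]
                discrepancies.append((g, o, per))

    lost = []
    if "dimensional" in frames and nd_frames:
        visible: set[str] = set()
        for f in nd_frames:
            set_id = int(f[3:])
            for symbols in grouping_symbols(set_id).values():
                visible |= set(symbols)
        for i in range(n_cells):
            g, o, sig = aligned["dimensional"][i]
            for p in sorted(sig - visible):
                lost.append((p, g, o))

    grid = {f: {(g, o): frozenset(s) for (g, o, s) in aligned[f].values()} for f in frames}
    return ComparisonReport(grid=grid, discrepancies=tuple(discrepancies),
                            lost_parameters=tuple(lost))


def run_study(config: StudyConfig | None = None, **kw) -> StudyResult:
    """Run every configured frame and assemble the comparison report.

    Deterministic for a fixed config: the LHS streams are seed+name keyed and
    evaluation order does not influence any result.
    """
    config = config or StudyConfig(**kw)
    frames = {}
    for frame in config.frames:
        frames[frame] = run_frame(frame, config)
    report = None
    if len(config.frames) > 1:
        grids = {name: fr.significance() for name, fr in frames.items()}
        report = report_discrepancies(grids)
    return StudyResult(config=config, frames=frames, report=report)
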