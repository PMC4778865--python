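"""The Species Accumulation Index and the end-to-end surrogacy evaluation.

SAI = (S - R) / (O - R), where for a given number of sites p

* S is the species count represented by the surrogate selection (here: sites
  chosen to span beta-diversity space),
* R is the mean species count of random selections of the same size, and
* O is the best achievable species count.

SAI is 1 when the surrogate matches the optimum, 0 when it is no better than
random, and negative (unbounded below) when it is worse than random; an SAI
of 0.6 means the surrogate realised 60% of the possible improvement over
random selection.  The pipeline evaluates SAI at a set of retained fractions
of the landscape and reports the unweighted mean, flagging a fraction as
significant when S exceeds the upper bound of the 95% confidence interval on
the mean R of the random replicates.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from ._seeds import stage_seed_sequence
from .benchmarks import (core_area_removal, optimal_curve, random_accumulation,
                         species_represented)
from .community import OccurrenceMatrix, jaccard_dissimilarity
from .ordination import OrdinationConfig, best_ordination
from .pmedian import make_demand_grid, select_pmedian

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FRACTIONS",
    "SurrogacyConfig",
    "AccumulationPoint",
    "SAIReport",
    "PipelineStageError",
    "sai",
    "evaluate_surrogacy",
    "export_report",
]

#: retained fractions of the landscape at which SAI is evaluated
DEFAULT_FRACTIONS = (0.15, 0.20, 0.25, 0.30, 0.35)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class SurrogacyConfig:
    fractions: tuple = DEFAULT_FRACTIONS
    ordination: OrdinationConfig = field(default_factory=OrdinationConfig)
    resolution: int = 100
    n_starts: int = 32
    pool: int = 10
    n_reps: int = 1000

    def snapshot(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        return d


@dataclass(frozen=True)
class AccumulationPoint:
    fraction: float
    p: int
    S: int
    R: float
    R_lo: float   # 2.5th percentile of random species counts
    R_hi: float   # 97.5th percentile of random species counts
    R_se: float   # standard error of the mean R
    O: float

    def __post_init__(self):
        if not (self.R_lo - 1e-9 <= self.R <= self.R_hi + 1e-9):
            raise ValueError("R must lie within its confidence bounds")
        if self.S > self.O:
            raise ValueError("S must not exceed O (apply the O-raising rule first)")


@dataclass(frozen=True)
class SAIReport:
    points: tuple
    sai_values: tuple
    significant: tuple
    mean_sai: float
    stress: float
    method: str
    seed: int
    config: dict
    selections: tuple = ()
    coordinates: np.ndarray | None = field(default=None, repr=False)


def sai(S: float, R: float, O: float) -> float:
    """Species Accumulation Index (S - R) / (O - R).

    Returns NaN with a warning when O == R (a saturated instance where random
    selection already reaches the optimum); raises when O < R, which violates
    the benchmark contract.
    """
    if O < R:
        raise ValueError(f"optimal benchmark O={O} below random baseline R={R}")
    if O == R:
        warnings.warn("SAI undefined: O == R (saturated instance)", stacklevel=2)
        return float("nan")
    return (S - R) / (O - R)


def _stage_seed(master: int, label: str) -> int:
    return int(stage_seed_sequence(master, label).generate_state(1)[0] & 0x7FFFFFFF)


def evaluate_surrogacy(m: OccurrenceMatrix, fractions=None,
                       config: SurrogacyConfig | None = None, seed: int = 0,
                       selector=None, stage_log: list | None = None) -> SAIReport:
    """Full pipeline: dissimilarity -> ordination -> p-median -> S vs O and R.

    ``selector(coords, grid, p, seed) -> site indices`` may replace the
    p-median surrogate (used to inject optimal or random selections when
    calibrating the index).  All randomness derives from ``seed``.
    """
    config = config or SurrogacyConfig()
    if fractions is not None:
        config = replace(config, fractions=tuple(fractions))
    if not m.presence.any(axis=1).all() or not m.presence.any(axis=0).all():
        raise ValueError("matrix has empty sites or species; run clean_matrix first")

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap with stage name
            raise PipelineStageError(name, exc) from exc
        if stage_log is not None:
            stage_log.append({"stage": name,
                              "elapsed_s": round(time.perf_counter() - t0, 3)})
        return out

    n = m.n_sites
    d = stage("dissimilarity", jaccard_dissimilarity, m)
    ord_cfg = replace(config.ordination, seed=_stage_seed(seed, "ordination"))
    ordination = stage("ordination", best_ordination, d, ord_cfg)
    grid = stage("demand-grid", make_demand_grid, ordination.coordinates,
                 config.resolution)
    ps = [max(1, int(round(f * n))) for f in config.fractions]
    o_values = stage("optimal-benchmark", optimal_curve, m, ps)
    baseline = stage("random-baseline", random_accumulation, m, ps,
                     config.n_reps, _stage_seed(seed, "baseline"))

    points = []
    sai_values = []
    flags = []
    selections = []
    if selector is None:
        def selector(coords, grid, p, sel_seed):
            return select_pmedian(coords, grid, p, n_starts=config.n_starts,
                                  pool=config.pool, seed=sel_seed).selected
    for frac, p, O, R, lo, hi, ci_hi in zip(config.fractions, ps, o_values,
                                            baseline.mean, baseline.lo,
                                            baseline.hi, baseline.ci_hi()):
        sel = stage(f"selection-{frac:g}", selector, ordination.coordinates,
                    grid, p, _stage_seed(seed, f"selection-{frac:g}"))
        S = species_represented(m, sel)
        O_eff = float(O)
        if S > O_eff:
            warnings.warn(f"surrogate S={S} exceeds heuristic O={O_eff} at "
                          f"p={p}; raising O to S", stacklevel=2)
            O_eff = float(S)
        se = (ci_hi - R) / 1.959963984540054
        points.append(AccumulationPoint(fraction=float(frac), p=p, S=S,
                                        R=float(R), R_lo=float(lo),
                                        R_hi=float(hi), R_se=float(se),
                                        O=O_eff))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = sai(S, float(R), O_eff)
        sai_values.append(value)
        # significant: S above the upper 95% CI bound on the mean R
        flags.append(bool(S > ci_hi))
        selections.append(tuple(int(s) for s in sel))

    values = np.asarray(sai_values, dtype=float)
    if np.isnan(values).any():
        warnings.warn("SAI is NaN at one or more fractions (saturated "
                      "instances); mean SAI propagates NaN", stacklevel=2)
    mean_sai = float(np.mean(values))  # NaN-propagating by design
    return SAIReport(points=tuple(points), sai_values=tuple(float(v) for v in values),
                     significant=tuple(flags), mean_sai=mean_sai,
                     stress=float(ordination.stress), method=ordination.method,
                     seed=int(seed), config=config.snapshot(),
                     selections=tuple(selections),
                     coordinates=ordination.coordinates)


def export_report(report: SAIReport, outdir) -> dict:
    """Write the per-fraction table, summary, and accumulation-curve files.

    Formatting is deterministic (shortest-roundtrip float repr), so
    re-exporting an identical report yields byte-identical files and parsing
    the table reproduces every number exactly.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = outdir / "surrogacy_report.tsv"
    lines = ["fraction\tp\tS\tR\tR_lo\tR_hi\tR_se\tO\tSAI\tsignificant"]
    for pt, value, flag in zip(report.points, report.sai_values, report.significant):
        lines.append("\t".join([repr(pt.fraction), str(pt.p), str(pt.S),
                                repr(pt.R), repr(pt.R_lo), repr(pt.R_hi),
                                repr(pt.R_se), repr(pt.O), repr(value),
                                str(int(flag))]))
    lines.append(f"mean\t\t\t\t\t\t\t\t{report.mean_sai!r}\t")
    table.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["table"] = table

    summary = outdir / "summary.json"
    summary.write_text(json.dumps({
        "mean_sai": report.mean_sai,
        "stress": report.stress,
        "ordination_method": report.method,
        "seed": report.seed,
        "n_significant": int(sum(report.significant)),
        "config": report.config,
        "selections": [list(s) for s in report.selections],
    }, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["summary"] = summary

    curve = outdir / "accumulation_curve.tsv"
    lines = ["p\tfraction\tO\tR\tR_lo\tR_hi"]
    for pt in report.points:
        lines.append("\t".join([str(pt.p), repr(pt.fraction), repr(pt.O),
                                repr(pt.R), repr(pt.R_lo), repr(pt.R_hi)]))
    curve.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["curve"] = curve
    return paths
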