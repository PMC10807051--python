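"""Sequential grid-search calibration.

Two stages, mirroring a semi-automated workflow for newly added gene
modules:

1. *Basal transcription rates*: genes are visited one at a time, in the
   order they were added.  If a gene's mRNA is not at steady state in a
   ligand-free simulation, its ``kTC_basal`` is grid-searched (15
   points spanning three log10 decades around the incumbent) to
   minimize the drift; the chosen value is frozen before the next gene
   is visited.

2. *Half-maximal constants K_A*: each transcriptional regulation is
   visited in addition order; its K_A is varied over the same grid, the
   model is simulated under every stimulation condition, and the value
   minimizing the summed fold-change SSE against the data is chosen and
   frozen.

Because the incumbent value sits on the (odd-length, log-symmetric)
grid, every coordinate step can only keep or decrease the objective, so
the full sweep is monotone — and, with no randomness anywhere, fully
deterministic.  Ties are broken toward the default (smallest log
distance, then the smaller value).  An optional bounded local
refinement between the best grid value's neighbors stands in for
by-hand adjustment and is off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .dynamics import DoseSpec, TimeCourse, drift_metric, simulate
from .expansion import ExpansionReport
from .model import Model

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """A log-uniform grid: ``points`` values over ``decades`` log10 decades
    centered on the default value (span default * 10^(+-decades/2))."""

    default: float
    decades: float = 3.0
    points: int = 15

    def __post_init__(self) -> None:
        if self.points < 2:
            raise ValueError("grid needs at least 2 points")
        if self.decades <= 0:
            raise ValueError("decades must be > 0")
        if self.default <= 0:
            raise ValueError("grid default must be > 0")


def log_grid(spec: GridSpec) -> np.ndarray:
    """Strictly increasing grid ``default * 10^linspace(-d/2, d/2, points)``."""
    exps = np.linspace(-spec.decades / 2.0, spec.decades / 2.0, spec.points)
    return spec.default * np.power(10.0, exps)


@dataclass
class FitResult:
    parameter: str
    grid: list[float]
    objective: list[float]
    chosen: float
    order_index: int
    skipped: bool = False
    refined: bool = False

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid": self.grid,
            "objective": self.objective,
            "chosen": self.chosen,
            "order_index": self.order_index,
            "skipped": self.skipped,
            "refined": self.refined,
        }


# condition name -> DataFrame indexed by time in seconds, one column per
# observable, values already on the fold-change scale (value / value at t=0)
DataSet = Mapping[str, pd.DataFrame]


def sse(
    sim: TimeCourse,
    data: pd.DataFrame,
    mapping: Mapping[str, str],
    fold_change: bool = True,
) -> float:
    """Sum of squared errors between a simulation and one data table.

    Simulated trajectories are interpolated to the data time points; with
    ``fold_change`` each trajectory is normalized to its value at the
    first data time point before comparison (matching fold-change data).
    """
    total = 0.0
    t = np.asarray(data.index, dtype=float)
    if t.min() < sim.times.min() - 1e-9 or t.max() > sim.times.max() + 1e-9:
        raise ValueError("data time points fall outside the simulated range")
    for obs in data.columns:
        species = mapping.get(obs, obs)
        y = np.interp(t, sim.times, sim.get(species))
        if fold_change:
            ref = y[0]
            if ref == 0:
                raise ValueError(f"cannot form fold change: {species} is 0 at t0")
            y = y / ref
        r = y - np.asarray(data[obs], dtype=float)
        total += float(np.dot(r, r))
    return total


def _choose(grid: np.ndarray, scores: np.ndarray, default: float) -> float:
    """Argmin with ties broken toward the default (log distance, then smaller)."""
    best = np.min(scores)
    cand = grid[np.isclose(scores, best, rtol=1e-12, atol=0.0)]
    dist = np.abs(np.log10(cand) - np.log10(default))
    cand = cand[np.isclose(dist, dist.min(), rtol=1e-12, atol=1e-15)]
    return float(np.min(cand))


def fit_basal_rates(
    model: Model,
    order: Sequence[str],
    duration_s: float = 48 * 3600.0,
    drift_tol: float = 0.01,
    decades: float = 3.0,
    points: int = 15,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[Model, list[FitResult]]:
    """Sequentially steady a set of genes' basal transcription rates.

    Returns a fitted copy of the model and one :class:`FitResult` per
    gene (marked ``skipped`` when the mRNA already passes the drift
    tolerance).  If no grid value meets the tolerance, the argmin is
    kept with a warning.
    """
    work = model.copy()
    results: list[FitResult] = []
    for k, gene in enumerate(order):
        if gene not in work.genes:
            raise ValueError(f"unknown gene {gene}")
        mrna = work.mrna_species(gene)
        tc = simulate(work, duration_s, rtol=rtol, atol=atol)
        d0 = drift_metric(tc, mrna)
        if d0 <= drift_tol:
            results.append(FitResult(
                f"kTC_basal[{gene}]", [], [], work.genes[gene].kTC_basal, k,
                skipped=True,
            ))
            continue
        default = work.genes[gene].kTC_basal
        grid = log_grid(GridSpec(default, decades, points))
        drifts = np.empty_like(grid)
        for i, val in enumerate(grid):
            work.genes[gene].kTC_basal = float(val)
            try:
                tc = simulate(work, duration_s, rtol=rtol, atol=atol)
                drifts[i] = drift_metric(tc, mrna)
            except RuntimeError as exc:
                log.warning("simulation failed at kTC_basal=%g: %s", val, exc)
                drifts[i] = np.inf
        chosen = _choose(grid, drifts, default)
        if drifts.min() > drift_tol:
            log.warning(
                "gene %s: no grid value reaches drift <= %g (best %g); keeping argmin",
                gene, drift_tol, drifts.min(),
            )
        work.genes[gene].kTC_basal = chosen
        results.append(FitResult(
            f"kTC_basal[{gene}]", list(map(float, grid)),
            list(map(float, drifts)), chosen, k,
        ))
        work.log(f"fitted kTC_basal[{gene}] = {chosen:g} (drift {drifts.min():g})")
    return work, results


def fit_KA(
    model: Model,
    data: DataSet,
    conditions: Mapping[str, Sequence[DoseSpec]],
    mapping: Mapping[str, str],
    order: Sequence[tuple[str, str]] | None = None,
    decades: float = 3.0,
    points: int = 15,
    refine: bool = False,
    sweeps: int = 1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[Model, list[FitResult]]:
    """Sequential grid fit of TAR half-maximal constants against data.

    ``data`` maps condition names to fold-change tables (time in seconds
    as index); ``conditions`` maps the same names to dose lists.  TARs
    are visited in ``order`` (default: model order).  A simulation
    failure at a grid value scores +inf and is logged.  With ``refine``
    a bounded scalar minimization between the best value's grid
    neighbors mimics manual between-grid adjustment.

    ``sweeps > 1`` repeats the coordinate pass: every grid stays
    centered on the parameter's original default, so the incumbent is
    always on its grid and the objective is non-increasing across the
    whole sequence; extra sweeps let mutually coupled regulations relax
    toward a joint optimum that a single pass can miss.
    """
    if set(data) != set(conditions):
        raise ValueError("data and conditions must cover the same condition names")
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    work = model.copy()
    keys = list(order) if order is not None else [t.key for t in work.tars]
    duration = max(float(np.max(df.index)) for df in data.values())

    def objective() -> float:
        total = 0.0
        for cond, df in data.items():
            tc = simulate(work, duration, doses=conditions[cond], rtol=rtol, atol=atol)
            total += sse(tc, df, mapping)
        return total

    grids: dict[tuple[str, str], np.ndarray] = {}
    for key in keys:
        tar = work.find_tar(*key)
        if tar is None:
            raise ValueError(f"no TAR {key[0]}->{key[1]} in model")
        grids[key] = log_grid(GridSpec(tar.K_A, decades, points))

    results: dict[tuple[str, str], FitResult] = {}
    for sweep in range(sweeps):
        for k, key in enumerate(keys):
            tar = work.find_tar(*key)
            incumbent = tar.K_A
            grid = grids[key]
            scores = np.empty_like(grid)
            for i, val in enumerate(grid):
                tar.K_A = float(val)
                try:
                    scores[i] = objective()
                except RuntimeError as exc:
                    log.warning("simulation failed at K_A=%g for %s: %s", val, key, exc)
                    scores[i] = np.inf
            chosen = _choose(grid, scores, incumbent)
            refined = False
            if refine and np.isfinite(scores).all():
                j = int(np.argmin(np.abs(np.log10(grid) - np.log10(chosen))))
                lo = grid[max(j - 1, 0)]
                hi = grid[min(j + 1, len(grid) - 1)]
                if lo < hi:
                    def f(logv: float) -> float:
                        tar.K_A = 10.0 ** logv
                        return objective()

                    res = minimize_scalar(
                        f, bounds=(math.log10(lo), math.log10(hi)), method="bounded",
                        options={"xatol": 1e-3},
                    )
                    if res.fun <= scores.min():
                        chosen = float(10.0 ** res.x)
                        refined = True
            tar.K_A = chosen
            results[key] = FitResult(
                f"K_A[{key[0]}->{key[1]}]", list(map(float, grid)),
                list(map(float, scores)), chosen, k, refined=refined,
            )
            work.log(
                f"sweep {sweep + 1}: fitted K_A[{key[0]}->{key[1]}] = {chosen:g}"
            )
    return work, [results[key] for key in keys]


def enumerate_free_parameters(model: Model, report: ExpansionReport) -> list[str]:
    """The free-parameter inventory of an expansion: one K_A per added
    regulation plus the mRNA and protein degradation rate of every added
    gene."""
    params: list[str] = []
    for entry in report.provenance:
        if entry["entity"] == "tar":
            params.append(f"K_A[{entry['id']}]")
    for entry in report.provenance:
        if entry["entity"] == "gene":
            params.append(f"kTCd[{entry['id']}]")
            params.append(f"kTLd[{entry['id']}]")
    return params
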