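"""Deterministic ODE assembly and integration.

State vector layout: first the active-copy count of every gene (the
gene on/off process is integrated as its deterministic expectation,
``dg/dt = kG_ac (GCN - g) - kG_in g``), then every species
concentration in nM.

Per gene, the gene module contributes

* transcription: ``flux = g_active * kTC_basal * (1 + sum_act h) *
  prod_rep (1 - h)`` in molecules/s, converted to nM/s through the
  mRNA's compartment volume;
* mRNA degradation ``kTCd * [mRNA]``.

Translation, protein degradation and everything else (ligand/TF stubs,
base-model reactions) are ordinary rate laws whose formulas are
compiled once with sympy and evaluated on the state vector.

Dosing is a step change of a ligand species' concentration at an onset
time; the trajectory is integrated piecewise between onsets with a
stiff solver (BDF, rtol 1e-8, atol 1e-10 by default).  Regulator and
formula inputs are clamped at zero inside the right-hand side so small
solver-induced negative excursions cannot produce unphysical fluxes,
while the linear degradation terms keep their restoring force.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .associations import ACTIVATOR
from .model import Model, TARInteraction

log = logging.getLogger(__name__)


def hill(x: float, K: float, n: float) -> float:
    """Hill activation fraction ``x^n / (x^n + K^n)`` in [0, 1).

    Monotone increasing in x; 0 at x=0 and 1/2 at x=K for any n.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if x < 0:
        raise ValueError("concentration must be >= 0")
    if x == 0.0:
        return 0.0
    # logistic form in log space: overflow-safe for extreme x/K ratios
    t = n * (np.log(x) - np.log(K))
    if t >= 0:
        return float(1.0 / (1.0 + np.exp(-t)))
    return float(np.exp(t) / (1.0 + np.exp(t)))


def transcription_flux(
    gene, tars: Sequence[TARInteraction], state: Mapping[str, float],
    active_copies: float | None = None,
) -> float:
    """Transcription flux (molecules/s) for one gene at a state.

    ``g_active * kTC_basal * (1 + sum_activators h) * prod_repressors (1-h)``;
    with no TARs this reduces to basal transcription.  Raises on negative
    regulator concentrations (the integrator clamps internally instead).
    """
    g = gene.copy_number * gene.active_fraction if active_copies is None else active_copies
    act, rep = 0.0, 1.0
    for t in tars:
        x = state[t.regulator]
        if x < 0:
            raise ValueError(f"negative concentration for regulator {t.regulator}")
        h = hill(x, t.K_A, t.n_A)
        if t.sign == ACTIVATOR:
            act += h
        else:
            rep *= 1.0 - h
    return g * gene.kTC_basal * (1.0 + act) * rep


@dataclass(frozen=True)
class DoseSpec:
    """A step change of a ligand species' concentration at an onset time."""

    species: str
    concentration_nm: float
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration_nm < 0:
            raise ValueError("dose concentration must be >= 0")


@dataclass
class TimeCourse:
    """Simulation output: times (s) and species-by-time values in nM.

    Gene active-copy trajectories are kept separately in
    ``gene_values``.  ``provenance`` records the model hash, solver
    settings and doses for reproducibility.
    """

    times: np.ndarray
    species: list[str]
    values: np.ndarray  # shape (n_species, n_times)
    genes: list[str] = field(default_factory=list)
    gene_values: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def get(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]

    def get_gene(self, gene: str) -> np.ndarray:
        return self.gene_values[self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=self.species)
        df.insert(0, "time_s", self.times)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


class RHSAssemblyError(ValueError):
    """A rate-law formula references a symbol that cannot be resolved."""


def build_rhs(model: Model):
    """Compile the model into ``f(t, y) -> dy/dt``.

    Returns ``(rhs, y0, gene_names, species_names)``; the initial state
    has gene copies at their on/off equilibrium and species at their
    table initial concentrations.
    """
    genes = list(model.genes.values())
    species_names = list(model.species)
    ng, ns = len(genes), len(species_names)
    sidx = {n: i + ng for i, n in enumerate(species_names)}

    # per-gene structure: mRNA index, nM-per-molecule conversion, TARs
    gene_rows = []
    for gi, g in enumerate(genes):
        mrna = model.mrna_species(g.gene)
        vol = model.species_volume(mrna)
        conv = 1e9 / (6.02214076e23 * vol)
        tars = [
            (sidx[t.regulator], t.sign == ACTIVATOR, t.K_A, t.n_A)
            for t in model.tars_targeting(g.gene)
        ]
        gene_rows.append((gi, sidx[mrna], conv, g, tars))

    # compile rate laws: substitute parameter values, lambdify over species
    compiled = []
    for rl in model.ratelaws.values():
        expr = sp.sympify(rl.formula)
        expr = expr.subs({sp.Symbol(k): v for k, v in rl.parameters.items()})
        free = {str(s) for s in expr.free_symbols}
        unknown = free - set(species_names)
        if unknown:
            raise RHSAssemblyError(
                f"ratelaw {rl.id}: unresolved symbols {sorted(unknown)}"
            )
        args = sorted(free)
        fn = sp.lambdify([sp.Symbol(a) for a in args], expr, "numpy")
        arg_idx = [sidx[a] for a in args]
        net = [(sidx[name], coef) for name, coef in rl.net_stoichiometry().items()]
        compiled.append((rl.id, fn, arg_idx, net))

    y0 = np.empty(ng + ns)
    for gi, g in enumerate(genes):
        y0[gi] = g.copy_number * g.active_fraction
    for name, i in sidx.items():
        y0[i] = model.species[name].initial_nm

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        yc = np.maximum(y, 0.0)  # clamp only where used as a flux input
        for gi, mi, conv, g, tars in gene_rows:
            gact = yc[gi]
            dy[gi] = g.kG_ac * (g.copy_number - y[gi]) - g.kG_in * y[gi]
            act, rep = 0.0, 1.0
            for ri, is_act, K, n in tars:
                x = yc[ri]
                h = x**n / (x**n + K**n) if x > 0 else 0.0
                if is_act:
                    act += h
                else:
                    rep *= 1.0 - h
            flux_nm = gact * g.kTC_basal * (1.0 + act) * rep * conv
            dy[mi] += flux_nm - g.kTCd * y[mi]
        for _, fn, arg_idx, net in compiled:
            v = float(fn(*(yc[arg_idx])))
            for i, coef in net:
                dy[i] += coef * v
        return dy

    return rhs, y0, [g.gene for g in genes], species_names


def _model_hash(model: Model) -> str:
    h = hashlib.sha256()
    h.update(repr(sorted(model.counts.items())).encode())
    for rl in model.ratelaws.values():
        h.update(f"{rl.id}|{rl.reaction}|{rl.formula}|{sorted(rl.parameters.items())}".encode())
    for t in model.tars:
        h.update(f"{t.tar_id}|{t.sign}|{t.K_A}|{t.n_A}".encode())
    for g in model.genes.values():
        h.update(f"{g.gene}|{g.copy_number}|{g.kG_ac}|{g.kG_in}|{g.kTC_basal}|{g.kTCd}".encode())
    for s in model.species.values():
        h.update(f"{s.name}|{s.initial_nm}".encode())
    return h.hexdigest()[:16]


def simulate(
    model: Model,
    duration_s: float,
    doses: Sequence[DoseSpec] = (),
    n_points: int = 241,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    pre_equilibrate_s: float = 0.0,
) -> TimeCourse:
    """Integrate the model for ``duration_s`` seconds under dose events.

    Doses are concentration steps applied at their onset times.  An
    optional pre-equilibration integrates the dose-free system for
    ``pre_equilibrate_s`` before t=0 and starts the reported trajectory
    from its end state (unnecessary for models whose initial state is
    already a fixed point by construction).
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    model.validate()
    rhs, y0, gene_names, species_names = build_rhs(model)
    ng = len(gene_names)

    if t_eval is None:
        t_eval = np.linspace(0.0, duration_s, n_points)
    t_eval = np.asarray(t_eval, dtype=float)

    def integrate(y_start, t0, t1, eval_pts):
        sol = solve_ivp(
            rhs, (t0, t1), y_start, method=method, rtol=rtol, atol=atol,
            t_eval=eval_pts, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={sol.t[-1] if len(sol.t) else t0:.6g} s: {sol.message}"
            )
        return sol

    y = y0.copy()
    if pre_equilibrate_s > 0:
        y = integrate(y, 0.0, pre_equilibrate_s, None).y[:, -1]

    onsets = sorted({d.onset_s for d in doses})
    boundaries = [0.0] + [t for t in onsets if 0.0 < t < duration_s] + [duration_s]
    if onsets and onsets[0] < 0:
        raise ValueError("dose onset must be >= 0")

    ys = np.empty((len(y), len(t_eval)))
    filled = np.zeros(len(t_eval), dtype=bool)
    sindex = {n: i + ng for i, n in enumerate(species_names)}
    t_cur = 0.0
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        for d in doses:
            if d.onset_s == b0:
                if d.species not in sindex:
                    raise ValueError(f"dose species {d.species} not in model")
                y[sindex[d.species]] = d.concentration_nm
        mask = (t_eval >= b0) & (t_eval <= b1) & ~filled
        pts = t_eval[mask]
        sol = integrate(y, b0, b1, pts if len(pts) else None)
        if len(pts):
            ys[:, mask] = sol.y
            filled |= mask
        y = sol.y[:, -1] if sol.y.shape[1] else y
        t_cur = b1

    tc = TimeCourse(
        times=t_eval,
        species=species_names,
        values=ys[ng:],
        genes=gene_names,
        gene_values=ys[:ng],
        provenance={
            "model_hash": _model_hash(model),
            "solver": {"method": method, "rtol": rtol, "atol": atol},
            "doses": [(d.species, d.concentration_nm, d.onset_s) for d in doses],
            "duration_s": duration_s,
            "pre_equilibrate_s": pre_equilibrate_s,
        },
    )
    return tc


def steady_state_check(
    tc: TimeCourse,
    species: Sequence[str],
    rel_tol: float = 0.01,
    eps: float = 1e-12,
) -> dict[str, bool]:
    """True per species iff |end - start| / max(start, eps) <= rel_tol.

    The boundary is inclusive: a drift of exactly ``rel_tol`` passes.
    """
    out: dict[str, bool] = {}
    for name in species:
        v = tc.get(name)
        drift = abs(v[-1] - v[0]) / max(abs(v[0]), eps)
        out[name] = bool(drift <= rel_tol)
    return out


def drift_metric(tc: TimeCourse, species: str, eps: float = 1e-12) -> float:
    v = tc.get(species)
    return float(abs(v[-1] - v[0]) / max(abs(v[0]), eps))
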