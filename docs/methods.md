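# Methods

This note documents the modeling choices, parameter conventions and
known limitations of `memgrow`. It is written for users who want to
understand what the package computes and what the bundled synthetic
fixtures do and do not demonstrate.

## Model representation

A model is five tab-delimited tables (first column = row identifier,
header row required, empty cell = absent, floats written with `repr` so
read∘write is byte-exact):

| table | contents |
|---|---|
| `Compartments.txt` | name, volume (liters) |
| `Species.txt` | name, compartment, initial concentration (nM), kind (mRNA / protein / phosphoprotein / other) |
| `RatelawsNoSM.txt` | reaction string (`A + 2 B -> C`), kinetic formula, named parameters |
| `GeneReg.txt` | transcriptional regulations: regulator species → target gene, sign, K_A (nM), n_A |
| `OmicsData.txt` | per-gene module: copy number, kG_ac, kG_in, kTC_basal, kTCd, mRNA count |

The dialect is this package's own; it follows the *structure* of
tab-delimited model-definition table sets (compartments / species /
rate laws / gene regulation / omics) without reproducing any particular
project's column layout. Internal time unit is seconds; half-lives are
accepted in hours and converted at the reader boundary. Species
concentrations are nM; gene states are absolute copy counts; the
molecules↔nM bridge is the compartment volume, always read from the
Compartments table (never a hard-coded constant).

Gene on/off states are *not* species: they live in the gene record and
are integrated as a deterministic expected-active-copy ODE
(`dg/dt = kG_ac (GCN − g) − kG_in g`). This keeps the species table to
mRNA + protein (+ phosphoprotein where measured) per gene — two species
and two rate laws (translation, protein degradation) per added gene —
with transcription and mRNA degradation handled by the gene module. In
the SBML export the gene state appears as a non-constant global
parameter driven by a rate rule, so the exported document reproduces
the internal dynamics exactly while keeping the species count
unchanged.

## Expansion semantics

Nodes of the association network are processed in order of first
appearance in the edge list; nodes already present as genes are skipped
(logged). For a new gene, rate constants derive from omics inputs:

- `kTCd = ln2 / t½(mRNA)`, `kTLd = ln2 / t½(protein)` (1/s);
- `kTC_basal = kTCd · mRNA_count · (kG_in + kG_ac)/(kG_ac · GCN)`
  (molecules/s per active copy), which makes the measured mRNA count
  the fixed point of the mRNA ODE at on/off equilibrium;
- `kTL = [P] · kTLd / [mRNA]`, making the measured protein level the
  fixed point of the protein ODE. Zero mRNA is a hard error by default
  (a floor can be passed explicitly) to avoid a silently infinite rate.

Missing omics fields fall back to the mean of the corresponding value
over existing genes (nonzero entries only) and are recorded in the
report's `defaults_used`. Gene on/off rates are never measured and
always inherit the base-model means.

Every edge yields two directed regulations, one per endpoint, signed by
the coefficient (strictly by sign; magnitude is ignored). The regulator
species is the gene's transcription-factor form: `<gene>_act` when the
model defines an activated species (mirroring nuclear-TF conventions),
otherwise the free protein. `K_A` defaults to half the regulator's
initial concentration; a regulator sitting at zero (activated forms
before stimulation) takes half the model-wide median positive protein
concentration instead, logged. `n_A = 4` for all new regulations.

**Deduplication and autoregulation.** Exact (regulator, target, sign)
duplicates collapse, keeping the first. A self-association produces two
*coincident* directed candidates, so exactly one survives — as an
autoregulation, which is kept by default (`allow_autoregulation=False`
drops it). This is why a 14-edge list with one self-association yields
27 regulations from 28 candidates: an odd regulation count is only
reachable through a self-edge, and positive autoregulation (IRF1 being
the canonical example) is mechanistically standard. The combination
rule for multiple regulators on one promoter is
`(1 + Σ h_act) · Π (1 − h_rep)`: activators add to a preserved basal
leak, repressors multiply it down. This form is one of several in use
in the field; it was chosen because basal transcription survives when
no activator is present, and it is isolated in one function should a
different convention be needed.

**Basal rebalancing.** After regulation creation, the basal rate of
every targeted gene is divided by its regulation factor `T` evaluated at
the initial state (`rebalance_basal=True`, the default). The
omics-derived state is then an exact fixed point of the *expanded*
system — the analytic limit of the numerical basal-rate calibration
stage. With `rebalance_basal=False` the raw formulas are kept and
`fit_basal_rates` does the same job by grid search. Stability at that
fixed point is not guaranteed in general (Hill regulation with n = 4
can in principle produce multistability), but with K_A at half the
regulator concentration the Hill terms sit in their flat region and all
bundled fixtures are verified stable by simulation.

Expansion is all-or-nothing (built on a copy, returned only on
success), idempotent, and reports counts that provably equal the model
deltas, with per-entity provenance.

## Simulation

`scipy.integrate.solve_ivp` with the BDF stiff method, `rtol 1e-8`,
`atol 1e-10` nM. Rate-law formulas are parsed once with sympy
(unresolved symbols are an assembly error naming the rate law) and
lambdified over the state vector. Doses are concentration steps of a
ligand species at onset times; the trajectory is integrated piecewise
between onsets. State values are clamped at zero *inside* flux
evaluations only, so solver-induced negative excursions (bounded by the
tolerances) cannot generate unphysical fluxes while linear degradation
keeps its restoring force; trajectories are never clipped for output.
Identical model + solver settings + doses give bit-identical output.

## Calibration

Both stages use the same log-uniform grid: `points` values (default 15)
spanning `decades` (default 3) log₁₀ decades *centered* on the default,
i.e. default × 10^±1.5. The centered reading was chosen over one-sided
readings because it is the only one that can both raise and lower a
parameter; the span and count are configurable.

1. **Basal rates** — genes visited one at a time in addition order; a
   gene whose mRNA drifts ≤ 1% (relative, inclusive) over the
   ligand-free window is skipped; otherwise `kTC_basal` takes the
   drift-minimizing grid value and is frozen. The 1% tolerance is this
   package's choice.
2. **K_A** — regulations visited in addition order; for each grid value
   both stimulation conditions are simulated and the fold-change SSE
   against the data is summed; the minimizer is frozen. Fold change is
   value(t)/value(t₀) at the data's first time point. Simulation
   failures score +∞ and are logged. Ties break toward the incumbent
   (log distance, then the smaller value) — minimal deviation from
   initialization. Because the incumbent sits on the odd-length grid,
   the total SSE is non-increasing across the entire sequence. An
   optional bounded scalar refinement between the best value's grid
   neighbors (`refine=True`) replaces by-hand between-grid adjustment
   and is off by default so results are pure grid outputs. `sweeps > 1`
   repeats the pass over fixed grids, letting mutually coupled
   regulations relax further; the default is a single pass.

**Identifiability.** The symmetric two-regulations-per-edge rule makes
parameters mutually compensating by construction: a noise-free dataset
can often be reproduced exactly at a parameter combination different
from the generating one (a sloppy manifold). The bundled recovery
experiment (`fixtures.ka_recovery_experiment`) therefore shifts one
K_A at a time two grid steps off its default, refits the whole
sequence, and accepts either recovery within one grid step or a
compensated fit whose RMS residual per fold-change point is ≤ 0.05
(below any realistic measurement noise). Single-parameter
identifiability is not guaranteed and is deliberately reported rather
than assumed.

## Knockouts

A knockout zeroes the gene's copy number, basal transcription rate and
the initial concentrations of its mRNA, protein, phosphoprotein and
activated-TF species; translation/degradation constants are untouched
(their substrates are zero), and the gene's regulations remain in the
model — a zero-concentration regulator contributes nothing as an
activator and fully releases as a repressor. The gene's products are
then identically zero for all time. Readout effect is the maximum (and
terminal) relative deviation from the wild type,
`|ko − wt| / max(|wt|, ε)` with ε tied to the readout's wild-type
scale; "observable" means exceeding a configurable threshold
(default 5% — the effect size below which a deviation is unlikely to be
distinguishable from fit uncertainty; the threshold is a package
choice). A reachability analysis over the model's influence graph
(species/gene nodes, edges from flux inputs to net-changed outputs and
from regulators to target mRNAs) provides a soundness oracle: a
knocked-out gene with no directed path to a readout must leave it
unchanged to solver tolerance.

## Synthetic fixtures

The toy base model emulates a signaling model with an interferon
module at minimal scale: a 1 pL cell, a handful of gene-expression
modules (STAT1, SOCS1, MYC by default) with log-uniform synthetic omics
(mRNA 1–10³ molecules/cell, protein 10⁻²–10³ nM, mRNA half-life 1–24 h,
protein half-life 10–100 h, 2 gene copies — ranges chosen to bracket
typical mammalian measurements), symmetric gene switching at
5×10⁻³ 1/s, and a ligand→TF stub: IFNG converts STAT1 to STAT1_act
(1e-3 nM⁻¹s⁻¹, deactivation 8e-4 s⁻¹) under negative feedback from
SOCS1 protein; STAT1_act transcriptionally activates SOCS1 (K_A = 0.2 ×
STAT1 level). SOCS1 half-lives are fixed short (2 h mRNA, 10 h protein)
so the feedback closes within the 48 h window, producing the canonical
transient TF activation. EGF drives an inert MYC_act arm, giving the
calibration a control condition. All randomness flows from a single
seed; regeneration is bit-identical.

Synthetic data tables sample a dense-early/sparse-late grid (0, 1, 4,
8, 24, 48 h), fold-changed to t₀, with optional multiplicative
lognormal noise (CV default 5%).

The candidate association list (`fixtures.candidate_subnetwork`) is a
**synthetic stand-in**: it reproduces the documented *shape* of the
interferon/PD-L1 candidate module — nine genes, fourteen signed
connections, one positive IRF1 self-association — with invented
coefficients. Likewise `make_module_network` embeds it in a synthetic
297-node / 321-edge background whose filler edges avoid the anchor
genes, so seed-filtering recovers the candidate list exactly.

What passing tests on these fixtures shows: the count arithmetic,
steady-state self-consistency, calibration mechanics and knockout
soundness of the machinery. What they do not show: agreement with any
real measured time course, real association coefficients, or
biological conclusions about specific genes — those require the actual
omics inputs, which users supply through the same readers.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
deliberately small scale — a 3-gene base, the 9-gene candidate
expansion (29 species) for structural checks, and a 2-new-gene /
3-edge expansion for fitting and screening (the recovery experiment
alone is ~300 stiff 48 h integrations). These sizes were chosen so the
whole validation runs in about a minute while still exercising every
code path; the machinery itself has no size assumptions beyond memory.

## Known limitations

- Base-model rate laws are evaluated as written; there is no algebraic
  simplification or conservation-law detection.
- Gene switching is deterministic (expected active copies); the hybrid
  stochastic mode of large single-cell frameworks is out of scope, so
  cell-to-cell variability is not represented.
- SBML import is a summary/round-trip checker, not a full model
  reconstructor; models are authored in the table dialect.
- The regulation combination rule and the knockout threshold are
  conventions (documented above), not measured quantities.
- Antimony text export is not provided; SBML L3V2 is the exchange
  format.
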