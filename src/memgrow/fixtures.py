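"""Synthetic toy models, networks, omics tables and ground-truth data.

Everything here is generated from a single seed so fixtures are
bit-reproducible, and everything is consistent by construction: a toy
base model simulated without ligand sits at its analytic steady state.

The toy base model stands in for a large signaling model with an
interferon sub-module.  It contains a handful of fully parameterized
gene-expression modules (STAT1 among them, the overlap gene the
expansion assumes), plus a minimal ligand-to-transcription-factor stub:
IFNG converts STAT1 protein into an active TF form (STAT1_act) with
first-order deactivation and negative feedback through SOCS1 protein,
and STAT1_act transcriptionally activates SOCS1.  This reproduces the
canonical transient TF activation / delayed feedback shape without any
receptor-level detail.  A second inert ligand (EGF -> MYC_act) provides
a control stimulation condition.

``candidate_subnetwork`` is a SYNTHETIC stand-in for the published
IFN-gamma/PD-L1 candidate association list (9 genes, 14 signed
connections, one self-association on IRF1); the real supplementary list
is not redistributed here, only its documented shape and sign structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .associations import AssociationNetwork, network_from_edges
from .dynamics import DoseSpec, simulate
from .expansion import OmicsRecord, write_omics_table
from .model import (
    Compartment, GeneRecord, Model, RateLaw, SpeciesRecord, TARInteraction,
)
from . import rates
from .units import hours_to_seconds, mpc_to_nm

log = logging.getLogger(__name__)

# stimulation doses used throughout: EGF 1.5625 nM, IFN-gamma 1.1834 nM
EGF_DOSE_NM = 1.5625
IFNG_DOSE_NM = 1.1834

SAMPLE_TIMES_H = (0.0, 1.0, 4.0, 8.0, 24.0, 48.0)


def standard_conditions() -> dict[str, list[DoseSpec]]:
    """The two stimulation conditions used for K_A calibration."""
    return {
        "egf": [DoseSpec("EGF", EGF_DOSE_NM)],
        "egf+ifng": [DoseSpec("EGF", EGF_DOSE_NM), DoseSpec("IFNG", IFNG_DOSE_NM)],
    }


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the toy-model family; the seed fixes all randomness."""

    n_base_genes: int = 3
    n_new_genes: int = 8
    n_edges: int = 14
    fraction_negative: float = 0.25
    seed: int = 0
    volume_l: float = 1e-12  # order of a mammalian cell
    k_act_ifng: float = 1e-3   # 1/(nM s): IFNG-driven STAT1 activation
    k_deact_ifng: float = 8e-4  # 1/s
    k_act_egf: float = 5e-4
    k_deact_egf: float = 5e-4
    kG_ac: float = 5e-3  # 1/s, gene activation (deterministic switching)
    kG_in: float = 5e-3  # 1/s, gene inactivation

    def __post_init__(self) -> None:
        n = self.n_new_genes + 1  # new genes plus the overlap gene
        if self.n_edges > n * (n + 1) // 2:
            raise ValueError("more edges requested than unordered pairs available")
        if self.n_base_genes < 1:
            raise ValueError("need at least one base gene (the overlap gene)")


_BASE_GENE_NAMES = ["STAT1", "SOCS1", "MYC"]


def base_gene_names(n: int) -> list[str]:
    names = _BASE_GENE_NAMES[:n]
    names += [f"BG{i}" for i in range(len(names) + 1, n + 1)]
    return names


def new_gene_names(n: int) -> list[str]:
    return [f"NG{i}" for i in range(1, n + 1)]


def make_synthetic_omics(
    genes: Sequence[str], seed: int = 0
) -> dict[str, OmicsRecord]:
    """Log-uniform synthetic omics per gene.

    mRNA 1-1000 molecules per cell, protein 0.01-1000 nM, mRNA half-life
    1-24 h, protein half-life 10-100 h, gene copy number 2.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, OmicsRecord] = {}
    for g in genes:
        out[g] = OmicsRecord(
            gene=g,
            mRNA_mpc=float(10 ** rng.uniform(0, 3)),
            protein_nM=float(10 ** rng.uniform(-2, 3)),
            mRNA_half_life_h=float(10 ** rng.uniform(0, np.log10(24))),
            protein_half_life_h=float(10 ** rng.uniform(1, 2)),
            copy_number=2.0,
        )
    return out


def make_toy_base_model(spec: ToySpec) -> Model:
    """Build the consistent toy base model described in the module docstring."""
    names = base_gene_names(spec.n_base_genes)
    omics = make_synthetic_omics(names, spec.seed)
    if "SOCS1" in omics:
        # fast feedback arm: short-lived mRNA and protein
        omics["SOCS1"].mRNA_half_life_h = 2.0
        omics["SOCS1"].protein_half_life_h = 10.0

    model = Model(f"toy_base_seed{spec.seed}")
    model.add_compartment(Compartment("Cell", spec.volume_l))

    for g in names:
        rec = omics[g]
        kTCd = rates.mrna_degradation_rate(rec.mRNA_half_life_h)
        kTLd = rates.protein_degradation_rate(rec.protein_half_life_h)
        kTCb = rates.basal_transcription_rate(
            kTCd, rec.mRNA_mpc, spec.kG_in, spec.kG_ac, rec.copy_number
        )
        mrna_nm = mpc_to_nm(rec.mRNA_mpc, spec.volume_l)
        kTL = rates.translation_rate(rec.protein_nM, kTLd, mrna_nm)
        mrna, prot = model.mrna_species(g), model.protein_species(g)
        model.add_species(SpeciesRecord(mrna, "Cell", mrna_nm, "mRNA"))
        model.add_species(SpeciesRecord(prot, "Cell", rec.protein_nM, "protein"))
        model.add_ratelaw(RateLaw(
            f"vTL_{g}", f"{mrna} -> {mrna} + {prot}", f"kTL*{mrna}", {"kTL": kTL}
        ))
        model.add_ratelaw(RateLaw(f"vPD_{g}", f"{prot} -> ", f"kTLd*{prot}", {"kTLd": kTLd}))
        model.add_gene(GeneRecord(
            g, rec.copy_number, spec.kG_ac, spec.kG_in, kTCb, kTCd, rec.mRNA_mpc
        ))

    # ligand -> TF stubs
    model.add_species(SpeciesRecord("IFNG", "Cell", 0.0, "other", "ligand"))
    model.add_species(SpeciesRecord("EGF", "Cell", 0.0, "other", "ligand"))
    model.add_species(SpeciesRecord("STAT1_act", "Cell", 0.0, "protein", "active TF"))
    k_fb = 0.25 * omics["SOCS1"].protein_nM if "SOCS1" in omics else 1e9
    model.add_ratelaw(RateLaw(
        "vActSTAT1", "STAT1 -> STAT1_act",
        "k_act*IFNG*STAT1/(1 + SOCS1/K_fb)" if "SOCS1" in omics
        else "k_act*IFNG*STAT1",
        {"k_act": spec.k_act_ifng, "K_fb": k_fb},
    ))
    model.add_ratelaw(RateLaw(
        "vDeactSTAT1", "STAT1_act -> STAT1", "k_deact*STAT1_act",
        {"k_deact": spec.k_deact_ifng},
    ))
    if "MYC" in omics:
        model.add_species(SpeciesRecord("MYC_act", "Cell", 0.0, "protein", "active TF"))
        model.add_ratelaw(RateLaw(
            "vActMYC", "MYC -> MYC_act", "k_act*EGF*MYC", {"k_act": spec.k_act_egf}
        ))
        model.add_ratelaw(RateLaw(
            "vDeactMYC", "MYC_act -> MYC", "k_deact*MYC_act",
            {"k_deact": spec.k_deact_egf},
        ))
    if "SOCS1" in omics:
        # canonical IFNG -> active STAT1 -> SOCS1 induction
        model.add_tar(TARInteraction(
            "STAT1_act", "SOCS1", "activator",
            K_A=0.2 * omics["STAT1"].protein_nM, n_A=4.0,
        ))
    model.validate()
    model.log(f"toy base model built: {model.counts}")
    return model


def make_toy_network(spec: ToySpec) -> AssociationNetwork:
    """Random signed association network over the new genes plus STAT1.

    A spanning tree guarantees every gene appears; remaining edges are
    unique random pairs.  Coefficient magnitudes are uniform in
    [0.05, 1), negative with probability ``fraction_negative``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nodes = ["STAT1"] + new_gene_names(spec.n_new_genes)
    pairs: list[tuple[str, str]] = []
    used: set[frozenset] = set()
    order = nodes.copy()
    for i in range(1, len(order)):  # spanning tree rooted at STAT1
        j = int(rng.integers(0, i))
        if len(pairs) >= spec.n_edges:
            break
        pairs.append((order[j], order[i]))
        used.add(frozenset((order[j], order[i])))
    all_pairs = [
        (a, b) for ai, a in enumerate(nodes) for b in nodes[ai:]
        if frozenset((a, b)) not in used
    ]
    idx = rng.permutation(len(all_pairs))
    for k in idx:
        if len(pairs) >= spec.n_edges:
            break
        a, b = all_pairs[int(k)]
        pairs.append((a, b))
        used.add(frozenset((a, b)))
    rows = []
    for a, b in pairs:
        mag = float(rng.uniform(0.05, 1.0))
        sign = -1.0 if rng.random() < spec.fraction_negative else 1.0
        rows.append((a, b, sign * mag))
    return network_from_edges(rows)


def candidate_subnetwork() -> AssociationNetwork:
    """SYNTHETIC stand-in for the IFN-gamma/PD-L1 candidate list.

    Nine genes, fourteen signed connections, including a positive IRF1
    self-association — the shape under which two directed regulation
    candidates coincide and exactly one collapses in expansion (27
    regulations from 28 candidates).  Coefficients are invented, only
    their signs carry meaning.
    """
    rows = [
        ("STAT1", "IRF1", 0.62),
        ("STAT1", "CD274", 0.45),
        ("STAT1", "BST2", 0.38),
        ("IRF1", "CD274", 0.51),
        ("IRF1", "BST2", 0.33),
        ("IRF1", "ACSL5", 0.22),
        ("IRF1", "CLIC2", 0.18),
        ("IRF1", "HIST2H2AA3", 0.27),
        ("IRF1", "METAP2", -0.21),
        ("IRF1", "FAM83D", -0.16),
        ("IRF1", "IRF1", 0.31),
        ("CD274", "BST2", 0.29),
        ("CD274", "FAM83D", -0.12),
        ("CD274", "METAP2", -0.19),
    ]
    return network_from_edges(rows)


CANDIDATE_GENES = (
    "ACSL5", "BST2", "CD274", "CLIC2", "FAM83D",
    "HIST2H2AA3", "IRF1", "METAP2", "STAT1",
)

SEED_GENES = ("IRF1", "CD274", "PDCD1", "STAT1")


def make_module_network(seed: int = 0) -> AssociationNetwork:
    """Synthetic genome-scale association module: 297 nodes, 321 edges.

    Embeds :func:`candidate_subnetwork` (whose edges all touch IRF1,
    CD274 or STAT1) in a background of filler genes none of which touch
    the anchor genes, so that filtering to the canonical seed set
    recovers exactly the 9-gene / 14-edge candidate list.
    """
    rng = np.random.default_rng(seed)
    cand = candidate_subnetwork()
    n_filler = 297 - cand.n_nodes
    filler = [f"ZZFILL{i}" for i in range(1, n_filler + 1)]
    rows = [(e.gene1, e.gene2, e.coefficient) for e in cand.edges]
    used: set[frozenset] = {e.pair for e in cand.edges}

    def coef() -> float:
        mag = float(rng.uniform(0.05, 1.0))
        return mag if rng.random() < 0.7 else -mag

    # spanning chain over filler genes keeps them all present
    for a, b in zip(filler[:-1], filler[1:]):
        rows.append((a, b, coef()))
        used.add(frozenset((a, b)))
    while len(rows) < 321:
        a, b = (filler[int(i)] for i in rng.integers(0, n_filler, 2))
        if a == b or frozenset((a, b)) in used:
            continue
        rows.append((a, b, coef()))
        used.add(frozenset((a, b)))
    net = network_from_edges(rows)
    assert net.n_nodes == 297 and net.n_edges == 321
    return net


def make_ground_truth_timecourses(
    model: Model,
    conditions: Mapping[str, Sequence[DoseSpec]],
    observables: Mapping[str, str],
    times_h: Sequence[float] = SAMPLE_TIMES_H,
    noise_cv: float = 0.0,
    seed: int = 0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, pd.DataFrame]:
    """Simulate the model per condition and emit fold-change data tables.

    ``observables`` maps observable names to species.  Values are
    sampled on a dense-early/sparse-late grid (default 0, 1, 4, 8, 24,
    48 h), fold-changed to t=0, and optionally corrupted with
    multiplicative lognormal noise of the given coefficient of
    variation (applied to raw values before fold-changing; t=0 included).
    """
    rng = np.random.default_rng(seed)
    times_s = np.array([hours_to_seconds(t) for t in times_h], dtype=float)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    out: dict[str, pd.DataFrame] = {}
    for cond, doses in conditions.items():
        tc = simulate(
            model, float(times_s[-1]), doses=doses, t_eval=times_s,
            rtol=rtol, atol=atol,
        )
        cols = {}
        for obs, species in observables.items():
            y = tc.get(species).copy()
            if sigma > 0:
                y = y * rng.lognormal(mean=0.0, sigma=sigma, size=y.shape)
            if y[0] == 0:
                raise ValueError(f"observable {obs} is 0 at t=0; cannot fold-change")
            cols[obs] = y / y[0]
        df = pd.DataFrame(cols, index=pd.Index(times_s, name="time_s"))
        out[cond] = df
    return out


def ka_recovery_experiment(
    model: Model,
    new_tar_keys: Sequence[tuple[str, str]],
    shift_keys: Sequence[tuple[str, str]] | None = None,
    shift_steps: float = 2.0,
    points: int = 15,
    decades: float = 3.0,
    sweeps: int = 1,
) -> list[dict]:
    """Ground-truth K_A recovery protocol for an expanded model.

    One experiment per entry of ``shift_keys`` (default: the first and
    last regulation in generation order): the chosen K_A is shifted off
    its default by ``shift_steps`` grid steps, noise-free fold-change
    data are generated from that ground-truth model under both standard
    stimulation conditions, and the full sequential grid fit is run from
    the defaults in generation order.

    Each result records the shifted parameter's grid-step recovery error
    and the initial/final total SSE of the fit.  Because mutually
    coupled regulations can compensate for one another, a sloppy
    direction may absorb the shift: the fit then reproduces the data
    essentially exactly at a different parameter combination, which the
    final SSE (per data point) makes visible.
    """
    from .calibration import fit_KA

    step = decades / (points - 1)
    if shift_keys is None:
        shift_keys = [new_tar_keys[0], new_tar_keys[-1]]
    conds = standard_conditions()
    observables = {}
    for g in model.genes:
        mrna = model.mrna_species(g)
        if any(t.target_gene == g for key in new_tar_keys
               for t in model.tars if t.key == key):
            observables[mrna] = mrna
    if not observables:
        observables = {model.mrna_species(g): model.mrna_species(g)
                       for g in model.genes}
    n_points = len(conds) * len(SAMPLE_TIMES_H) * len(observables)

    results = []
    for key in shift_keys:
        true_model = model.copy()
        tar = true_model.find_tar(*key)
        truth = tar.K_A * 10 ** (shift_steps * step)
        tar.K_A = truth
        data = make_ground_truth_timecourses(true_model, conds, observables)
        fitted, fits = fit_KA(
            model, data, conds, mapping={}, order=new_tar_keys,
            points=points, decades=decades, sweeps=sweeps,
        )
        f = next(f for f in fits if new_tar_keys[f.order_index] == key)
        center = len(fits[0].grid) // 2
        results.append({
            "parameter": f.parameter,
            "truth": truth,
            "chosen": f.chosen,
            "grid_step_error": abs(np.log10(f.chosen / truth)) / step,
            "initial_sse": fits[0].objective[center],
            "final_sse": min(fits[-1].objective),
            "n_data_points": n_points,
            "fits": fits,
        })
    return results


def write_data_tables(data: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Write the per-condition fold-change tables as one long TSV."""
    frames = []
    for cond, df in data.items():
        d = df.reset_index()
        d.insert(0, "condition", cond)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_data_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for cond, sub in df.groupby("condition", sort=False):
        out[str(cond)] = sub.drop(columns="condition").set_index("time_s")
    return out


def write_fixture_set(
    spec: ToySpec, directory: str | Path
) -> dict[str, Path]:
    """Emit a full fixture set: model tables, network TSV, omics TSV."""
    from .associations import write_edges
    from .model import write_model_tables

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model = make_toy_base_model(spec)
    paths = write_model_tables(model, directory / "model")
    net = make_toy_network(spec)
    net_path = directory / "network.tsv"
    write_edges(net, net_path)
    omics = make_synthetic_omics(net.nodes, spec.seed + 2)
    omics_path = directory / "omics.tsv"
    write_omics_table(omics, omics_path)
    return {"model": directory / "model", "network": net_path, "omics": omics_path,
            **{f"table_{k}": v for k, v in paths.items()}}
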