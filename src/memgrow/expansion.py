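"""Model expansion: association network + omics tables -> new model content.

For every network node absent from the base model, a full
gene-expression module is created (gene record, mRNA and protein
species, translation and protein-degradation rate laws) with rate
constants derived from omics measurements (:mod:`memgrow.rates`).  Every
association edge then becomes two directed transcriptional regulations
(TARs), one per endpoint, signed by the coefficient: positive ->
activator, negative -> repressor.  Hill coefficients default to 4 and
half-maximal constants K_A to half the regulator's initial
concentration.

A self-edge (a gene associated with itself) yields two coincident
directed candidates; the exact duplicate collapses and the surviving
autoregulation is kept by default (``allow_autoregulation=False``
drops it instead).

Expansion is all-or-nothing: it works on a copy and only returns it on
success, together with an :class:`ExpansionReport` whose counts equal
the model deltas and whose provenance lists the origin of every added
entity.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import rates
from .associations import ACTIVATOR, AssociationNetwork, classify_edge
from .model import GeneRecord, Model, RateLaw, SpeciesRecord, TARInteraction
from .units import mpc_to_nm

log = logging.getLogger(__name__)

DEFAULT_HILL_COEFFICIENT = 4.0


@dataclass
class OmicsRecord:
    """Per-gene parameterization inputs.

    Units: mRNA in molecules per cell, protein (and optional
    phosphoprotein) in nM, half-lives in hours, copy number in genomic
    copies.  Missing fields (``None``) fall back to base-model means at
    expansion time and are logged in ``defaults_used``.
    """

    gene: str
    mRNA_mpc: float | None = None
    protein_nM: float | None = None
    mRNA_half_life_h: float | None = None
    protein_half_life_h: float | None = None
    copy_number: float | None = None
    phospho_nM: float | None = None


OmicsInputs = Mapping[str, OmicsRecord]

_OMICS_COLUMNS = [
    "Gene", "mRNA_mpc", "Protein_nM", "mRNAHalfLife_h",
    "ProteinHalfLife_h", "CopyNumber", "Phospho_nM",
]


def read_omics_table(path: str | Path) -> dict[str, OmicsRecord]:
    """Read the per-gene omics TSV (header required, empty cell = absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _OMICS_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: omics table missing columns {missing}")

    def val(row, col):
        raw = str(row.get(col, "")).strip()
        return float(raw) if raw and raw.lower() != "nan" else None

    out: dict[str, OmicsRecord] = {}
    for _, row in df.iterrows():
        g = row["Gene"].strip().upper()
        out[g] = OmicsRecord(
            g, val(row, "mRNA_mpc"), val(row, "Protein_nM"),
            val(row, "mRNAHalfLife_h"), val(row, "ProteinHalfLife_h"),
            val(row, "CopyNumber"), val(row, "Phospho_nM"),
        )
    return out


def write_omics_table(omics: OmicsInputs, path: str | Path) -> None:
    rows = []
    for rec in omics.values():
        rows.append([
            rec.gene,
            *("" if v is None else repr(float(v)) for v in (
                rec.mRNA_mpc, rec.protein_nM, rec.mRNA_half_life_h,
                rec.protein_half_life_h, rec.copy_number, rec.phospho_nM)),
        ])
    pd.DataFrame(rows, columns=_OMICS_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class ExpansionReport:
    genes_added: int = 0
    species_added: int = 0
    ratelaws_added: int = 0
    tars_added: int = 0
    provenance: list[dict] = field(default_factory=list)
    defaults_used: list[str] = field(default_factory=list)
    skipped_genes: list[str] = field(default_factory=list)
    collapsed_tars: list[str] = field(default_factory=list)
    dropped_self_tars: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "genes_added": self.genes_added,
            "species_added": self.species_added,
            "ratelaws_added": self.ratelaws_added,
            "tars_added": self.tars_added,
            "provenance": self.provenance,
            "defaults_used": self.defaults_used,
            "skipped_genes": self.skipped_genes,
            "collapsed_tars": self.collapsed_tars,
            "dropped_self_tars": self.dropped_self_tars,
        }


def init_KA(regulator_initial_nm: float, fallback_nm: float | None = None) -> tuple[float, bool]:
    """Default half-maximal constant: half the regulator's concentration.

    Returns ``(K_A, used_fallback)``.  A regulator sitting at zero (e.g.
    an activated TF form absent before stimulation) takes half the
    model-wide median positive protein concentration instead, so K_A
    stays strictly positive.
    """
    if regulator_initial_nm < 0:
        raise ValueError("regulator concentration must be >= 0")
    if regulator_initial_nm > 0:
        return regulator_initial_nm / 2.0, False
    if fallback_nm is None or fallback_nm <= 0:
        raise ValueError(
            "regulator at 0 nM and no positive fallback concentration available"
        )
    return fallback_nm / 2.0, True


def _median_protein_conc(model: Model) -> float | None:
    vals = [
        s.initial_nm
        for s in model.species.values()
        if s.kind == "protein" and s.initial_nm > 0
    ]
    return statistics.median(vals) if vals else None


def _gene_means(model: Model) -> dict[str, float]:
    """Mean gene-module parameters over existing genes, nonzero entries only."""
    out: dict[str, float] = {}
    for attr in ("kG_ac", "kG_in", "kTCd", "copy_number", "mRNA_count"):
        vals = [getattr(g, attr) for g in model.genes.values() if getattr(g, attr) > 0]
        if vals:
            out[attr] = sum(vals) / len(vals)
    # mean protein degradation rate over existing protein-degradation ratelaws
    ktlds = [
        rl.parameters["kTLd"]
        for rl in model.ratelaws.values()
        if "kTLd" in rl.parameters and rl.parameters["kTLd"] > 0
    ]
    if ktlds:
        out["kTLd"] = sum(ktlds) / len(ktlds)
    return out


def make_gene_entities(
    gene: str,
    omics: OmicsRecord | None,
    model: Model,
    report: ExpansionReport,
    compartment: str | None = None,
) -> bool:
    """Add one gene-expression module to ``model`` in place.

    Creates the mRNA and protein species (plus a phosphoprotein species
    when a phospho measurement exists), the translation and
    protein-degradation rate laws, and the gene record.  Missing omics
    fields fall back to base-model means, recorded in
    ``report.defaults_used``.  Returns False (no-op) if the gene already
    exists.
    """
    if gene in model.genes:
        report.skipped_genes.append(gene)
        model.log(f"gene {gene} already in model; nothing added")
        return False
    if compartment is None:
        compartment = next(iter(model.compartments))
    vol = model.compartments[compartment].volume_l
    means = _gene_means(model)

    def resolve(value: float | None, mean_key: str, what: str) -> float:
        if value is not None:
            return value
        if mean_key not in means:
            raise ValueError(
                f"gene {gene}: no omics value and no model default for {what}"
            )
        report.defaults_used.append(f"{gene}:{what}")
        model.log(f"gene {gene}: {what} defaulted to base-model mean {means[mean_key]:g}")
        return means[mean_key]

    omics = omics or OmicsRecord(gene)
    mRNA_mpc = resolve(omics.mRNA_mpc, "mRNA_count", "mRNA_count")
    gcn = resolve(omics.copy_number, "copy_number", "copy_number")
    # gene on/off rates are never measured; always base-model means
    if means.get("kG_ac") is None or means.get("kG_in") is None:
        raise ValueError(f"gene {gene}: base model defines no gene on/off rates to inherit")
    kG_ac, kG_in = means["kG_ac"], means["kG_in"]

    if omics.mRNA_half_life_h is not None:
        kTCd = rates.mrna_degradation_rate(omics.mRNA_half_life_h)
    else:
        kTCd = resolve(None, "kTCd", "kTCd")
    if omics.protein_half_life_h is not None:
        kTLd = rates.protein_degradation_rate(omics.protein_half_life_h)
    else:
        kTLd = resolve(None, "kTLd", "kTLd")

    protein_nm = omics.protein_nM
    if protein_nm is None:
        med = _median_protein_conc(model)
        if med is None:
            raise ValueError(f"gene {gene}: no protein concentration and no model default")
        protein_nm = med
        report.defaults_used.append(f"{gene}:protein_nM")
        model.log(f"gene {gene}: protein concentration defaulted to median {med:g} nM")

    mrna_nm = mpc_to_nm(mRNA_mpc, vol)
    kTC_basal = rates.basal_transcription_rate(kTCd, mRNA_mpc, kG_in, kG_ac, gcn)
    kTL = rates.translation_rate(protein_nm, kTLd, mrna_nm)

    mrna = model.mrna_species(gene)
    prot = model.protein_species(gene)
    model.add_species(SpeciesRecord(mrna, compartment, mrna_nm, "mRNA"))
    model.add_species(SpeciesRecord(prot, compartment, protein_nm, "protein"))
    n_species = 2
    if omics.phospho_nM is not None:
        model.add_species(SpeciesRecord(
            model.phospho_species(gene), compartment, omics.phospho_nM, "phosphoprotein"
        ))
        n_species += 1
    model.add_ratelaw(RateLaw(
        f"vTL_{gene}", f"{mrna} -> {mrna} + {prot}",
        f"kTL*{mrna}", {"kTL": kTL},
    ))
    model.add_ratelaw(RateLaw(
        f"vPD_{gene}", f"{prot} -> ", f"kTLd*{prot}", {"kTLd": kTLd},
    ))
    model.add_gene(GeneRecord(gene, gcn, kG_ac, kG_in, kTC_basal, kTCd, mRNA_mpc))

    report.genes_added += 1
    report.species_added += n_species
    report.ratelaws_added += 2
    report.provenance.append({
        "entity": "gene", "id": gene, "species": n_species,
        "ratelaws": [f"vTL_{gene}", f"vPD_{gene}"],
    })
    model.log(f"added gene {gene}: {n_species} species, 2 ratelaws")
    return True


def edges_to_tars(
    net: AssociationNetwork,
    model: Model,
    report: ExpansionReport | None = None,
    allow_autoregulation: bool = True,
    hill_coefficient: float = DEFAULT_HILL_COEFFICIENT,
) -> list[TARInteraction]:
    """Create two directed TARs per association edge and add them to the model.

    The protein (or activated TF form) of each endpoint regulates the
    other endpoint's gene, with the sign of the shared coefficient.
    Exact (regulator, target, sign) duplicates collapse — for a
    self-edge the two directions coincide, so exactly one candidate
    survives.  Duplicates of TARs already present in the model are
    skipped, and self-regulations are dropped when
    ``allow_autoregulation`` is False.  All drops are logged.
    """
    report = report or ExpansionReport()
    fallback = _median_protein_conc(model)
    added: list[TARInteraction] = []
    seen: set[tuple[str, str, str]] = set(
        (t.regulator, t.target_gene, t.sign) for t in model.tars
    )
    for edge in net.edges:
        sign = classify_edge(edge)
        for src, tgt in ((edge.gene1, edge.gene2), (edge.gene2, edge.gene1)):
            if tgt not in model.genes:
                raise ValueError(f"edge endpoint {tgt} has no gene in the model")
            reg = model.regulator_species(src)
            if reg not in model.species:
                raise ValueError(f"regulator species {reg} missing for gene {src}")
            label = f"{reg}->{tgt}({sign})"
            if (reg, tgt, sign) in seen:
                report.collapsed_tars.append(label)
                model.log(f"TAR {label} duplicates an existing one; collapsed")
                continue
            seen.add((reg, tgt, sign))
            if not allow_autoregulation and src == tgt:
                report.dropped_self_tars.append(label)
                model.log(f"self-regulation {label} dropped")
                continue
            existing = model.find_tar(reg, tgt)
            if existing is not None:
                # same (regulator, target) with a different sign: keep first
                report.collapsed_tars.append(label)
                model.log(
                    f"TAR {label} conflicts with existing sign "
                    f"{existing.sign}; keeping first"
                )
                seen.add((reg, tgt, sign))
                continue
            ka, used_fallback = init_KA(model.species[reg].initial_nm, fallback)
            if used_fallback:
                report.defaults_used.append(f"K_A[{reg}->{tgt}]")
                model.log(f"K_A for {label} from median-protein fallback: {ka:g} nM")
            tar = TARInteraction(reg, tgt, sign, ka, hill_coefficient)
            model.add_tar(tar)
            seen.add((reg, tgt, sign))
            added.append(tar)
            report.tars_added += 1
            report.provenance.append({
                "entity": "tar", "id": tar.tar_id, "sign": sign,
                "edge": f"{edge.gene1}-{edge.gene2}",
                "coefficient": edge.coefficient, "K_A": ka,
            })
    return added


def tar_modulation_factor(model: Model, gene: str, state: Mapping[str, float]) -> float:
    """Transcription modulation by the TARs targeting ``gene`` at a state.

    ``(1 + sum_activators h) * prod_repressors (1 - h)`` with
    ``h(x; K, n) = x^n/(x^n + K^n)``.  Equals 1 with no TARs or with all
    regulators at zero, preserving basal transcription.
    """
    from .dynamics import hill  # local import to avoid a cycle

    act = 0.0
    rep = 1.0
    for t in model.tars_targeting(gene):
        h = hill(state[t.regulator], t.K_A, t.n_A)
        if t.sign == ACTIVATOR:
            act += h
        else:
            rep *= 1.0 - h
    return (1.0 + act) * rep


def expand_model(
    model: Model,
    net: AssociationNetwork,
    omics: OmicsInputs,
    allow_autoregulation: bool = True,
    rebalance_basal: bool = True,
    hill_coefficient: float = DEFAULT_HILL_COEFFICIENT,
) -> tuple[Model, ExpansionReport]:
    """Expand a base model with an association network; all-or-nothing.

    Nodes are processed in order of first appearance in the edge list
    ("order of species added"), then edges become TARs.  When
    ``rebalance_basal`` is set (default), the basal transcription rate
    of every gene targeted by new TARs is divided by the TAR modulation
    factor at the initial state, so the omics-derived state remains an
    exact fixed point of the expanded system — the analytic counterpart
    of the steady-state basal-rate calibration step.  Idempotent: a
    second expansion with the same network reports all-zero deltas.
    """
    work = model.copy()
    report = ExpansionReport()
    pre = work.counts

    for gene in net.nodes:
        make_gene_entities(gene, omics.get(gene), work, report)

    new_tars = edges_to_tars(
        net, work, report,
        allow_autoregulation=allow_autoregulation,
        hill_coefficient=hill_coefficient,
    )

    if rebalance_basal and new_tars:
        init_state = {s.name: s.initial_nm for s in work.species.values()}
        for gene in sorted({t.target_gene for t in new_tars}):
            factor = tar_modulation_factor(work, gene, init_state)
            if factor <= 0:
                work.log(
                    f"gene {gene}: TAR modulation factor {factor:g} at initial "
                    f"state; basal rate left unrebalanced"
                )
                continue
            g = work.genes[gene]
            g.kTC_basal = g.kTC_basal / factor
            work.log(
                f"gene {gene}: kTC_basal rebalanced by 1/{factor:.6g} to keep "
                f"the initial state a fixed point"
            )

    work.validate()
    post = work.counts
    deltas = {k: post[k] - pre[k] for k in pre}
    assert deltas["genes"] == report.genes_added
    assert deltas["species"] == report.species_added
    assert deltas["ratelaws"] == report.ratelaws_added
    assert deltas["tars"] == report.tars_added
    work.log(
        f"expansion: +{report.genes_added} genes, +{report.species_added} species, "
        f"+{report.ratelaws_added} ratelaws, +{report.tars_added} TARs"
    )
    return work, report
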