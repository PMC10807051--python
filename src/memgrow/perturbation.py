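"""In-silico single-gene knockouts and wild-type comparison.

A knockout sets a gene's copy number, mRNA, protein (and activated or
phosphorylated forms) to zero and silences its basal transcription, so
the gene's products are identically zero for all time; everything else
in the model is untouched.  Knockout trajectories are compared to the
wild type per readout species via the maximum and terminal relative
deviation, and genes are ranked by maximum effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .dynamics import DoseSpec, TimeCourse, simulate
from .model import Model

log = logging.getLogger(__name__)

DEFAULT_EFFECT_THRESHOLD = 0.05


def knockout(model: Model, gene: str) -> Model:
    """Return a copy of the model with ``gene`` fully knocked out.

    Zeroes the gene copy number, basal transcription rate, and the
    initial concentrations of the gene's mRNA, protein, phosphoprotein
    and activated-TF species where present.  Translation and degradation
    rate constants are left untouched (their substrates are zero).
    Idempotent; unknown genes raise with the available gene list.
    """
    if gene not in model.genes:
        raise ValueError(
            f"unknown gene {gene!r}; model genes: {sorted(model.genes)}"
        )
    ko = model.copy()
    g = ko.genes[gene]
    g.copy_number = 0.0
    g.kTC_basal = 0.0
    g.mRNA_count = 0.0
    for name in (
        ko.mrna_species(gene), ko.protein_species(gene),
        ko.phospho_species(gene), f"{gene}_act",
    ):
        if name in ko.species:
            ko.species[name].initial_nm = 0.0
    ko.log(f"knockout: {gene} gene, mRNA and protein levels set to zero")
    return ko


@dataclass
class KnockoutReport:
    gene: str
    readouts: list[str]
    max_deviation: dict[str, float] = field(default_factory=dict)
    terminal_deviation: dict[str, float] = field(default_factory=dict)
    threshold: float = DEFAULT_EFFECT_THRESHOLD

    @property
    def max_effect(self) -> float:
        return max(self.max_deviation.values(), default=0.0)

    @property
    def classification(self) -> str:
        return "observable" if self.max_effect > self.threshold else "negligible"

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "readouts": self.readouts,
            "max_deviation": self.max_deviation,
            "terminal_deviation": self.terminal_deviation,
            "threshold": self.threshold,
            "classification": self.classification,
        }


def compare_to_wildtype(
    tc_ko: TimeCourse,
    tc_wt: TimeCourse,
    readouts: Sequence[str],
    gene: str = "",
    threshold: float = DEFAULT_EFFECT_THRESHOLD,
) -> KnockoutReport:
    """Per-readout relative deviation of a knockout from the wild type.

    Deviation at each time is ``|ko - wt| / max(|wt|, eps)`` with eps a
    small floor tied to the readout's wild-type scale (guards readouts
    that start at zero).  Requires identical time grids.
    """
    if len(tc_ko.times) != len(tc_wt.times) or not np.allclose(tc_ko.times, tc_wt.times):
        raise ValueError("knockout and wild-type runs must share the time grid")
    rep = KnockoutReport(gene=gene, readouts=list(readouts), threshold=threshold)
    for r in readouts:
        wt = tc_wt.get(r)
        ko = tc_ko.get(r)
        eps = max(1e-6 * float(np.max(np.abs(wt))), 1e-12)
        dev = np.abs(ko - wt) / np.maximum(np.abs(wt), eps)
        rep.max_deviation[r] = float(np.max(dev))
        rep.terminal_deviation[r] = float(dev[-1])
    return rep


def screen_knockouts(
    model: Model,
    genes: Sequence[str],
    readouts: Sequence[str],
    doses: Sequence[DoseSpec] = (),
    duration_s: float = 48 * 3600.0,
    threshold: float = DEFAULT_EFFECT_THRESHOLD,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    pre_equilibrate_s: float = 0.0,
) -> list[KnockoutReport]:
    """Simulate every single-gene knockout and rank by maximum effect.

    The wild-type trajectory is computed once and reused.  Reports are
    sorted by decreasing maximum deviation (ties by gene name), so
    permuting the input gene list permutes nothing but itself.
    """
    tc_wt = simulate(
        model, duration_s, doses=doses, rtol=rtol, atol=atol,
        pre_equilibrate_s=pre_equilibrate_s,
    )
    reports = []
    for gene in genes:
        tc_ko = simulate(
            knockout(model, gene), duration_s, doses=doses, rtol=rtol, atol=atol,
            pre_equilibrate_s=pre_equilibrate_s,
        )
        reports.append(
            compare_to_wildtype(tc_ko, tc_wt, readouts, gene=gene, threshold=threshold)
        )
    return sorted(reports, key=lambda r: (-r.max_effect, r.gene))


def knockout_sources(model: Model, gene: str) -> list[str]:
    """Graph nodes silenced by knocking out ``gene``."""
    nodes = [f"gene:{gene}"]
    for name in (
        model.mrna_species(gene), model.protein_species(gene),
        model.phospho_species(gene), f"{gene}_act",
    ):
        if name in model.species:
            nodes.append(name)
    return nodes


def can_affect(model: Model, gene: str, readout: str) -> bool:
    """True iff a directed influence path runs from the gene's products
    to the readout species in the model's regulatory graph."""
    g = model.regulatory_graph()
    return any(
        nx.has_path(g, src, readout) for src in knockout_sources(model, gene)
        if src in g
    )
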