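"""Signed gene-gene association networks.

The expansion input is an edge list of statistical associations between
genes, typically Lasso coefficients from a multi-omics integration
pipeline.  Edges are undirected at this layer and carry a signed,
dimensionless coefficient; the sign decides whether the downstream
transcriptional regulation is activating (positive) or repressing
(negative).  Direction is introduced only by the expansion engine, which
creates one regulation per edge endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

log = logging.getLogger(__name__)

ACTIVATOR = "activator"
REPRESSOR = "repressor"

_COLUMNS = ("gene1", "gene2", "coefficient")


class AssociationFormatError(ValueError):
    """Raised when an edge-list file does not match the expected 3-column layout."""


@dataclass(frozen=True)
class AssociationEdge:
    """One undirected signed association between two genes.

    Gene symbols are stored normalized (trimmed, upper-case).  The
    coefficient must be finite and nonzero: the sign rule defines only
    activation and repression, so zero-weight edges are rejected upstream.
    """

    gene1: str
    gene2: str
    coefficient: float

    def __post_init__(self) -> None:
        if not self.gene1 or not self.gene2:
            raise ValueError("gene symbols must be non-empty")
        if not math.isfinite(self.coefficient) or self.coefficient == 0.0:
            raise ValueError(
                f"coefficient must be finite and nonzero "
                f"({self.gene1}-{self.gene2}: {self.coefficient!r})"
            )

    @property
    def pair(self) -> frozenset:
        """Unordered endpoint pair (a singleton frozenset for self-edges)."""
        return frozenset((self.gene1, self.gene2))

    @property
    def is_self_edge(self) -> bool:
        return self.gene1 == self.gene2


@dataclass
class AssociationNetwork:
    """A set of unique undirected signed edges plus the derived node set."""

    edges: list[AssociationEdge] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        """Unique gene symbols in order of first appearance across edges."""
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.gene1)
            seen.setdefault(e.gene2)
        return list(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


def normalize_symbol(symbol: str, aliases: Mapping[str, str] | None = None) -> str:
    """Trim and upper-case a gene symbol, then apply an optional alias map.

    The alias table (e.g. CD274 <-> PD-L1, PDCD1 <-> PD-1) is user
    supplied; keys and values are matched case-insensitively.
    """
    s = str(symbol).strip().upper()
    if aliases:
        canon = {str(k).strip().upper(): str(v).strip().upper() for k, v in aliases.items()}
        s = canon.get(s, s)
    return s


def classify_edge(edge: AssociationEdge | float) -> str:
    """Map a signed coefficient to a regulation sign.

    Positive associations become transcriptional activators, negative ones
    repressors; the magnitude plays no role.  Zero is rejected at load
    time, so a zero here is a programming error.
    """
    c = edge.coefficient if isinstance(edge, AssociationEdge) else float(edge)
    if c > 0:
        return ACTIVATOR
    if c < 0:
        return REPRESSOR
    raise ValueError("cannot classify a zero coefficient")


def _dedupe(edges: Iterable[AssociationEdge]) -> list[AssociationEdge]:
    out: list[AssociationEdge] = []
    seen: dict[frozenset, AssociationEdge] = {}
    for e in edges:
        prev = seen.get(e.pair)
        if prev is not None:
            log.warning(
                "duplicate unordered pair %s-%s (coefficient %g) collapsed; "
                "keeping first occurrence (%g)",
                e.gene1, e.gene2, e.coefficient, prev.coefficient,
            )
            continue
        seen[e.pair] = e
        out.append(e)
    return out


def network_from_edges(
    rows: Iterable[tuple[str, str, float]],
    aliases: Mapping[str, str] | None = None,
) -> AssociationNetwork:
    """Build a validated network from (gene1, gene2, coefficient) triples.

    Zero coefficients are dropped with a warning; duplicate unordered
    pairs keep the first occurrence.
    """
    edges: list[AssociationEdge] = []
    for g1, g2, c in rows:
        c = float(c)
        if c == 0.0:
            log.warning("dropping zero-coefficient edge %s-%s", g1, g2)
            continue
        edges.append(
            AssociationEdge(
                normalize_symbol(g1, aliases), normalize_symbol(g2, aliases), c
            )
        )
    return AssociationNetwork(_dedupe(edges))


def load_edges(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> AssociationNetwork:
    """Read a tab-separated edge list (gene1, gene2, coefficient).

    The header line ``gene1\\tgene2\\tcoefficient`` is optional.  Raises
    :class:`AssociationFormatError` for a wrong column count and
    ``ValueError`` with the offending row number for non-numeric
    coefficients.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    start = 0
    if lines:
        first = [f.strip() for f in lines[0].split("\t")]
        if [f.lower() for f in first[:3]] == list(_COLUMNS):
            start = 1
        elif len(first) != 3:
            raise AssociationFormatError(
                f"{path}: expected 3 tab-separated columns "
                f"(gene1, gene2, coefficient), got {len(first)}"
            )
    for i, line in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 3:
            raise AssociationFormatError(
                f"{path}:{i}: expected 3 columns, got {len(fields)}"
            )
        try:
            coef = float(fields[2])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i}: non-numeric coefficient {fields[2]!r}"
            ) from exc
        rows.append((fields[0], fields[1], coef))
    net = network_from_edges(rows, aliases)
    log.info("loaded %s: %d nodes, %d edges", path, net.n_nodes, net.n_edges)
    return net


def write_edges(net: AssociationNetwork, path: str | Path) -> None:
    """Write a network back out in the 3-column TSV dialect (with header)."""
    df = pd.DataFrame(
        [(e.gene1, e.gene2, repr(e.coefficient)) for e in net.edges],
        columns=list(_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def filter_to_seeds(
    net: AssociationNetwork,
    seeds: Sequence[str] | set[str],
    aliases: Mapping[str, str] | None = None,
) -> AssociationNetwork:
    """Keep exactly the edges touching at least one seed gene.

    This mirrors the sub-network selection step where a genome-scale
    association module is reduced to the interactions involving a small
    set of anchor genes before model expansion.
    """
    if not seeds:
        raise ValueError("seed set must be non-empty")
    seed_set = {normalize_symbol(s, aliases) for s in seeds}
    kept = [e for e in net.edges if e.gene1 in seed_set or e.gene2 in seed_set]
    return AssociationNetwork(list(kept))
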