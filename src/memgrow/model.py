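"""In-memory mechanistic model container and tab-delimited table I/O.

A :class:`Model` bundles compartments, species, gene records, rate laws
and transcriptional activator/repressor (TAR) interactions — the unit
that is read from disk, expanded with new genes, exported to SBML and
integrated as an ODE system.

On disk a model is a directory of five tab-delimited tables
(``Compartments.txt``, ``Species.txt``, ``RatelawsNoSM.txt``,
``GeneReg.txt``, ``OmicsData.txt``).  The dialect is documented per
table below: header row required, first column is the row identifier,
empty cells mean "absent", floats are written with ``repr`` so that a
read/write round trip is byte-exact.

Gene expression is split in two layers, mirroring large-scale signaling
model conventions:

* the *gene module* (OmicsData table / :class:`GeneRecord`): gene copy
  number, deterministic on/off switching rates ``kG_ac``/``kG_in``,
  basal transcription rate ``kTC_basal`` (molecules/s per active copy)
  and first-order mRNA degradation ``kTCd``;
* the *rate-law table*: every other reaction, including per-gene
  translation and protein degradation, written as explicit reaction
  strings with kinetic formulas in nM/s.
"""

from __future__ import annotations

import copy as _copy
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd
import sympy as sp

log = logging.getLogger(__name__)

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

TABLE_FILES = {
    "compartments": "Compartments.txt",
    "species": "Species.txt",
    "ratelaws": "RatelawsNoSM.txt",
    "genereg": "GeneReg.txt",
    "omicsdata": "OmicsData.txt",
}


class ModelIntegrityError(ValueError):
    """Cross-reference violation inside a model (dangling species, etc.)."""


def _check_ident(name: str, what: str) -> str:
    if not _IDENT.match(name):
        raise ValueError(f"{what} name {name!r} is not a valid identifier")
    return name


@dataclass
class Compartment:
    name: str
    volume_l: float
    annotation: str = ""

    def __post_init__(self) -> None:
        _check_ident(self.name, "compartment")
        if self.volume_l <= 0:
            raise ValueError(f"compartment {self.name}: volume must be > 0")


@dataclass
class SpeciesRecord:
    name: str
    compartment: str
    initial_nm: float
    kind: str = "other"  # mRNA | protein | phosphoprotein | other
    annotation: str = ""

    def __post_init__(self) -> None:
        _check_ident(self.name, "species")
        if self.initial_nm < 0:
            raise ValueError(f"species {self.name}: initial concentration < 0")
        if self.kind not in ("mRNA", "protein", "phosphoprotein", "other"):
            raise ValueError(f"species {self.name}: unknown kind {self.kind!r}")


@dataclass
class GeneRecord:
    """Gene-module parameters for one gene.

    ``kTC_basal`` is in molecules per second per active gene copy,
    ``kTCd``/``kG_ac``/``kG_in`` in 1/s, ``mRNA_count`` in molecules per
    cell.  ``copy_number`` may be zero only for knocked-out genes.
    """

    gene: str
    copy_number: float
    kG_ac: float
    kG_in: float
    kTC_basal: float
    kTCd: float
    mRNA_count: float

    def __post_init__(self) -> None:
        _check_ident(self.gene, "gene")
        for attr in ("kG_ac", "kG_in", "kTC_basal", "kTCd", "mRNA_count"):
            v = getattr(self, attr)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"gene {self.gene}: {attr} must be finite and >= 0")
        if self.copy_number < 0:
            raise ValueError(f"gene {self.gene}: copy_number must be >= 0")
        if self.kG_ac + self.kG_in <= 0:
            raise ValueError(f"gene {self.gene}: kG_ac + kG_in must be > 0")

    @property
    def active_fraction(self) -> float:
        """Equilibrium fraction of active gene copies, kG_ac/(kG_ac+kG_in)."""
        return self.kG_ac / (self.kG_ac + self.kG_in)


def parse_reaction(reaction: str) -> tuple[list[tuple[float, str]], list[tuple[float, str]]]:
    """Parse ``"A + 2 B -> C"`` into (reactants, products) stoichiometry lists.

    Either side may be empty (synthesis/degradation).
    """
    if "->" not in reaction:
        raise ValueError(f"reaction {reaction!r} must contain '->'")
    lhs, rhs = reaction.split("->", 1)

    def side(txt: str) -> list[tuple[float, str]]:
        out: list[tuple[float, str]] = []
        for term in txt.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                out.append((1.0, parts[0]))
            elif len(parts) == 2:
                out.append((float(parts[0]), parts[1]))
            else:
                raise ValueError(f"cannot parse reaction term {term!r}")
        return out

    return side(lhs), side(rhs)


def format_reaction(
    reactants: list[tuple[float, str]], products: list[tuple[float, str]]
) -> str:
    def side(terms: list[tuple[float, str]]) -> str:
        parts = []
        for coef, name in terms:
            parts.append(name if coef == 1 else f"{coef:g} {name}")
        return " + ".join(parts)

    return f"{side(reactants)} -> {side(products)}".strip()


@dataclass
class RateLaw:
    """One reaction with an explicit kinetic formula.

    ``formula`` is an arithmetic expression over species names and the
    parameter names in ``parameters``; it evaluates to a flux in nM/s in
    the compartment of the participating species.
    """

    id: str
    reaction: str
    formula: str
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_ident(self.id, "ratelaw")
        for k, v in self.parameters.items():
            _check_ident(k, f"ratelaw {self.id} parameter")
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"ratelaw {self.id}: parameter {k} must be finite and >= 0")
        parse_reaction(self.reaction)  # validates syntax

    @property
    def reactants(self) -> list[tuple[float, str]]:
        return parse_reaction(self.reaction)[0]

    @property
    def products(self) -> list[tuple[float, str]]:
        return parse_reaction(self.reaction)[1]

    def formula_symbols(self) -> set[str]:
        expr = sp.sympify(self.formula, evaluate=False)
        return {str(s) for s in expr.free_symbols}

    def net_stoichiometry(self) -> dict[str, float]:
        net: dict[str, float] = {}
        for coef, name in self.reactants:
            net[name] = net.get(name, 0.0) - coef
        for coef, name in self.products:
            net[name] = net.get(name, 0.0) + coef
        return {k: v for k, v in net.items() if v != 0.0}


@dataclass
class TARInteraction:
    """A directed transcriptional regulation: regulator protein -> target gene.

    The regulation enters the target's transcription flux as a Hill term
    ``h(x; K_A, n_A) = x^n / (x^n + K_A^n)``: activators multiply the
    basal flux by ``(1 + h)``, repressors by ``(1 - h)``.  Autoregulation
    (regulator is a product of the target gene itself) is permitted.
    """

    regulator: str
    target_gene: str
    sign: str  # activator | repressor
    K_A: float
    n_A: float = 4.0

    def __post_init__(self) -> None:
        _check_ident(self.regulator, "regulator species")
        _check_ident(self.target_gene, "target gene")
        if self.sign not in ("activator", "repressor"):
            raise ValueError(f"TAR {self.regulator}->{self.target_gene}: bad sign {self.sign!r}")
        if not self.K_A > 0:
            raise ValueError(f"TAR {self.regulator}->{self.target_gene}: K_A must be > 0")
        if self.n_A < 1:
            raise ValueError(f"TAR {self.regulator}->{self.target_gene}: n_A must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.regulator, self.target_gene)

    @property
    def tar_id(self) -> str:
        return f"{self.regulator}__{self.target_gene}"


class Model:
    """Container for one mechanistic model; see module docstring."""

    def __init__(self, name: str = "model"):
        self.name = name
        self.compartments: dict[str, Compartment] = {}
        self.species: dict[str, SpeciesRecord] = {}
        self.genes: dict[str, GeneRecord] = {}
        self.ratelaws: dict[str, RateLaw] = {}
        self.tars: list[TARInteraction] = []
        self.provenance: list[str] = []

    # -- construction -------------------------------------------------

    def add_compartment(self, c: Compartment) -> None:
        if c.name in self.compartments:
            raise ValueError(f"duplicate compartment {c.name}")
        self.compartments[c.name] = c

    def add_species(self, s: SpeciesRecord) -> None:
        if s.name in self.species:
            raise ValueError(f"duplicate species {s.name}")
        if s.compartment not in self.compartments:
            raise ModelIntegrityError(
                f"species {s.name} references unknown compartment {s.compartment}"
            )
        self.species[s.name] = s

    def add_gene(self, g: GeneRecord) -> None:
        if g.gene in self.genes:
            raise ValueError(f"duplicate gene {g.gene}")
        self.genes[g.gene] = g

    def add_ratelaw(self, rl: RateLaw) -> None:
        if rl.id in self.ratelaws:
            raise ValueError(f"duplicate ratelaw {rl.id}")
        self.ratelaws[rl.id] = rl

    def add_tar(self, t: TARInteraction) -> None:
        if any(t.key == u.key for u in self.tars):
            raise ValueError(f"duplicate TAR {t.regulator}->{t.target_gene}")
        self.tars.append(t)

    def log(self, msg: str) -> None:
        self.provenance.append(msg)
        log.info("%s: %s", self.name, msg)

    # -- conventions ---------------------------------------------------

    def mrna_species(self, gene: str) -> str:
        return f"mRNA_{gene}"

    def protein_species(self, gene: str) -> str:
        return gene

    def phospho_species(self, gene: str) -> str:
        return f"p{gene}"

    def regulator_species(self, gene: str) -> str:
        """The species acting as the gene's transcription factor.

        If the model defines an activated form ``<gene>_act`` (e.g. a
        phosphorylated/dimerized nuclear TF), that species carries the
        regulatory activity; otherwise the free protein does.
        """
        act = f"{gene}_act"
        return act if act in self.species else self.protein_species(gene)

    def tars_targeting(self, gene: str) -> list[TARInteraction]:
        return [t for t in self.tars if t.target_gene == gene]

    def find_tar(self, regulator: str, target_gene: str) -> TARInteraction | None:
        for t in self.tars:
            if t.key == (regulator, target_gene):
                return t
        return None

    # -- accounting ----------------------------------------------------

    @property
    def counts(self) -> dict[str, int]:
        return {
            "compartments": len(self.compartments),
            "genes": len(self.genes),
            "species": len(self.species),
            "ratelaws": len(self.ratelaws),
            "tars": len(self.tars),
            "parameters": self.parameter_count,
        }

    @property
    def parameter_count(self) -> int:
        """Total named constants: ratelaw parameters, 5 per gene record
        (copy number, on/off rates, basal transcription, mRNA
        degradation), 2 per TAR (K_A, n_A)."""
        n = sum(len(rl.parameters) for rl in self.ratelaws.values())
        n += 5 * len(self.genes)
        n += 2 * len(self.tars)
        return n

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity; raises :class:`ModelIntegrityError`."""
        if not self.compartments:
            raise ModelIntegrityError("model has no compartments")
        for s in self.species.values():
            if s.compartment not in self.compartments:
                raise ModelIntegrityError(
                    f"species {s.name}: unknown compartment {s.compartment}"
                )
        for g in self.genes:
            for sp_name in (self.mrna_species(g), self.protein_species(g)):
                if sp_name not in self.species:
                    raise ModelIntegrityError(f"gene {g}: missing species {sp_name}")
        for rl in self.ratelaws.values():
            for coef, name in rl.reactants + rl.products:
                if name not in self.species:
                    raise ModelIntegrityError(
                        f"ratelaw {rl.id}: unknown species {name}"
                    )
            unknown = rl.formula_symbols() - set(self.species) - set(rl.parameters)
            if unknown:
                raise ModelIntegrityError(
                    f"ratelaw {rl.id}: unresolved symbols {sorted(unknown)}"
                )
        seen: set[tuple[str, str]] = set()
        for t in self.tars:
            if t.regulator not in self.species:
                raise ModelIntegrityError(
                    f"TAR {t.regulator}->{t.target_gene}: unknown regulator species"
                )
            if t.target_gene not in self.genes:
                raise ModelIntegrityError(
                    f"TAR {t.regulator}->{t.target_gene}: unknown target gene"
                )
            if t.key in seen:
                raise ModelIntegrityError(f"duplicate TAR {t.regulator}->{t.target_gene}")
            seen.add(t.key)

    # -- misc ----------------------------------------------------------

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    def equals(self, other: "Model") -> bool:
        return (
            self.compartments == other.compartments
            and self.species == other.species
            and self.genes == other.genes
            and self.ratelaws == other.ratelaws
            and self.tars == other.tars
        )

    def species_volume(self, species: str) -> float:
        return self.compartments[self.species[species].compartment].volume_l

    def regulatory_graph(self) -> nx.DiGraph:
        """Directed influence graph over species and gene nodes.

        Edge u -> v means u appears in a flux that changes v: rate-law
        formula/reactant species point at net-changed species; gene nodes
        point at their mRNA; TAR regulators point at the target's mRNA;
        mRNA points at protein via the translation rate law (covered by
        the rate-law rule).  Used for zero-effect soundness checks of
        knockout screens.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        for gene in self.genes:
            gene_node = f"gene:{gene}"
            g.add_edge(gene_node, self.mrna_species(gene))
        for rl in self.ratelaws.values():
            inputs = set(rl.formula_symbols()) & set(self.species)
            inputs |= {name for _, name in rl.reactants}
            for out in rl.net_stoichiometry():
                for inp in inputs:
                    if inp != out:
                        g.add_edge(inp, out)
        for t in self.tars:
            g.add_edge(t.regulator, self.mrna_species(t.target_gene))
        return g


# ----------------------------------------------------------------------
# Tab-delimited table I/O
# ----------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def _params_to_str(params: dict[str, float]) -> str:
    return ";".join(f"{k}={_fmt(v)}" for k, v in params.items())


def _params_from_str(s: str) -> dict[str, float]:
    out: dict[str, float] = {}
    s = s.strip()
    if not s or s == "nan":
        return out
    for item in s.split(";"):
        k, v = item.split("=", 1)
        out[k.strip()] = float(v)
    return out


def write_model_tables(model: Model, directory: str | Path) -> dict[str, Path]:
    """Write the five-table representation; returns the file paths.

    ``read_model_tables(write_model_tables(m))`` reproduces the model
    exactly (floats via ``repr``, annotations byte-preserved).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(key: str, df: pd.DataFrame) -> None:
        p = directory / TABLE_FILES[key]
        df.to_csv(p, sep="\t", index=False)
        paths[key] = p

    emit("compartments", pd.DataFrame(
        [(c.name, _fmt(c.volume_l), c.annotation) for c in model.compartments.values()],
        columns=["Compartment", "VolumeLiters", "Annotation"],
    ))
    emit("species", pd.DataFrame(
        [(s.name, s.compartment, _fmt(s.initial_nm), s.kind, s.annotation)
         for s in model.species.values()],
        columns=["Species", "Compartment", "InitialConc_nM", "Kind", "Annotation"],
    ))
    emit("ratelaws", pd.DataFrame(
        [(rl.id, rl.reaction, rl.formula, _params_to_str(rl.parameters))
         for rl in model.ratelaws.values()],
        columns=["Ratelaw", "Reaction", "Formula", "Parameters"],
    ))
    emit("genereg", pd.DataFrame(
        [(t.tar_id, t.regulator, t.target_gene, t.sign, _fmt(t.K_A), _fmt(t.n_A))
         for t in model.tars],
        columns=["TAR", "Regulator", "TargetGene", "Sign", "K_A_nM", "n_A"],
    ))
    emit("omicsdata", pd.DataFrame(
        [(g.gene, _fmt(g.copy_number), _fmt(g.kG_ac), _fmt(g.kG_in),
          _fmt(g.kTC_basal), _fmt(g.kTCd), _fmt(g.mRNA_count))
         for g in model.genes.values()],
        columns=["Gene", "CopyNumber", "kGac_1ps", "kGin_1ps",
                 "kTCbasal_mpcps", "kTCd_1ps", "mRNA_mpc"],
    ))
    return paths


def read_model_tables(directory: str | Path, name: str | None = None) -> Model:
    """Read a model from its five-table directory and validate it.

    Missing tables raise ``FileNotFoundError``; dangling references raise
    :class:`ModelIntegrityError` naming the offending row.
    """
    directory = Path(directory)
    for key, fname in TABLE_FILES.items():
        if not (directory / fname).exists():
            raise FileNotFoundError(f"model table {fname} not found in {directory}")

    def read(key: str) -> pd.DataFrame:
        return pd.read_csv(
            directory / TABLE_FILES[key], sep="\t", dtype=str, keep_default_na=False
        )

    model = Model(name or directory.name)
    for _, row in read("compartments").iterrows():
        model.add_compartment(Compartment(
            row["Compartment"], float(row["VolumeLiters"]), row.get("Annotation", "")
        ))
    for _, row in read("species").iterrows():
        model.add_species(SpeciesRecord(
            row["Species"], row["Compartment"], float(row["InitialConc_nM"]),
            row["Kind"] or "other", row.get("Annotation", ""),
        ))
    for _, row in read("omicsdata").iterrows():
        model.add_gene(GeneRecord(
            row["Gene"], float(row["CopyNumber"]), float(row["kGac_1ps"]),
            float(row["kGin_1ps"]), float(row["kTCbasal_mpcps"]),
            float(row["kTCd_1ps"]), float(row["mRNA_mpc"]),
        ))
    for _, row in read("ratelaws").iterrows():
        model.add_ratelaw(RateLaw(
            row["Ratelaw"], row["Reaction"], row["Formula"],
            _params_from_str(row["Parameters"]),
        ))
    for _, row in read("genereg").iterrows():
        model.add_tar(TARInteraction(
            row["Regulator"], row["TargetGene"], row["Sign"],
            float(row["K_A_nM"]), float(row["n_A"]),
        ))
    model.validate()
    log.info("read model %s: %s", model.name, model.counts)
    return model
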