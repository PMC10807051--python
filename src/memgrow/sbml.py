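"""SBML Level 3 export of models and generic SBML enlargement.

The exported document mirrors the internal dynamics exactly:

* species carry their initial concentrations in nM;
* every internal rate law becomes one SBML reaction whose kinetic law
  embeds the formula, with rate-law constants as local parameters (so
  names cannot collide across reactions);
* the gene module is exported per gene as a transcription reaction
  (Hill TAR terms embedded in the kinetic law, regulators listed as
  modifiers, the active-copy count as a non-constant global parameter
  driven by a rate rule) plus an mRNA degradation reaction.

All outputs must pass libSBML's consistency check with zero errors;
identifier sanitization (non-alphanumerics to underscores) is applied
with a persisted mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import libsbml

from .associations import ACTIVATOR
from .model import Model, parse_reaction

log = logging.getLogger(__name__)

_AVOGADRO = 6.02214076e23


class SBMLExportError(ValueError):
    pass


def sanitize_id(name: str, mapping: dict[str, str] | None = None) -> str:
    """Map a name to a valid SBML SId; records renames in ``mapping``."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not sid or not re.match(r"[A-Za-z_]", sid[0]):
        sid = "_" + sid
    if mapping is not None and sid != name:
        mapping[name] = sid
        log.info("sanitized identifier %r -> %r", name, sid)
    return sid


def _check(obj, what: str):
    if obj is None:
        raise SBMLExportError(f"libSBML failed to create {what}")
    return obj


def _hill_term(reg: str, K: float, n: float) -> str:
    return f"({reg}^{n:g} / ({reg}^{n:g} + {K!r}^{n:g}))"


def _set_formula(kl: libsbml.KineticLaw, formula: str, context: str) -> None:
    # sympy/python power operator -> SBML L3 infix
    ast = libsbml.parseL3Formula(formula.replace("**", "^"))
    if ast is None:
        raise SBMLExportError(f"{context}: cannot parse formula {formula!r}")
    kl.setMath(ast)


def export_sbml(model: Model, path: str | Path | None = None) -> libsbml.SBMLDocument:
    """Build (and optionally write) a validated SBML L3V2 document."""
    model.validate()
    if not model.compartments:
        raise SBMLExportError("model has no compartments")
    idmap: dict[str, str] = {}

    doc = libsbml.SBMLDocument(3, 2)
    m = _check(doc.createModel(), "model")
    m.setId(sanitize_id(model.name, idmap))

    for c in model.compartments.values():
        comp = _check(m.createCompartment(), f"compartment {c.name}")
        comp.setId(sanitize_id(c.name, idmap))
        comp.setConstant(True)
        comp.setSize(c.volume_l)
        comp.setSpatialDimensions(3)

    for s in model.species.values():
        sb = _check(m.createSpecies(), f"species {s.name}")
        sb.setId(sanitize_id(s.name, idmap))
        sb.setCompartment(sanitize_id(s.compartment))
        sb.setInitialConcentration(s.initial_nm)
        sb.setHasOnlySubstanceUnits(False)
        sb.setBoundaryCondition(False)
        sb.setConstant(False)
        if s.annotation or s.kind != "other":
            sb.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                        f"<p>kind: {s.kind}. {s.annotation}</p></body>")

    # nM-per-molecule conversion factor, one global parameter per compartment
    for c in model.compartments.values():
        p = _check(m.createParameter(), "conversion parameter")
        p.setId(f"nm_per_molecule_{sanitize_id(c.name)}")
        p.setValue(1e9 / (_AVOGADRO * c.volume_l))
        p.setConstant(True)

    # ordinary rate laws
    for rl in model.ratelaws.values():
        rx = _check(m.createReaction(), f"reaction {rl.id}")
        rx.setId(sanitize_id(rl.id, idmap))
        rx.setReversible(False)
        reactants, products = parse_reaction(rl.reaction)
        for coef, name in reactants:
            sr = rx.createReactant()
            sr.setSpecies(sanitize_id(name))
            sr.setStoichiometry(coef)
            sr.setConstant(True)
        for coef, name in products:
            sr = rx.createProduct()
            sr.setSpecies(sanitize_id(name))
            sr.setStoichiometry(coef)
            sr.setConstant(True)
        in_rxn = {name for _, name in reactants + products}
        for sym in sorted(rl.formula_symbols() & set(model.species)):
            if sym not in in_rxn:
                mod = rx.createModifier()
                mod.setSpecies(sanitize_id(sym))
        kl = _check(rx.createKineticLaw(), f"kinetic law {rl.id}")
        for k, v in rl.parameters.items():
            lp = kl.createLocalParameter()
            lp.setId(sanitize_id(k))
            lp.setValue(v)
        _set_formula(kl, rl.formula, f"ratelaw {rl.id}")

    # gene modules: global parameters + rate rule + transcription/degradation
    for g in model.genes.values():
        gid = sanitize_id(g.gene)
        for pname, val, const in (
            (f"GCN_{gid}", g.copy_number, True),
            (f"kGac_{gid}", g.kG_ac, True),
            (f"kGin_{gid}", g.kG_in, True),
            (f"kTCb_{gid}", g.kTC_basal, True),
            (f"kTCd_{gid}", g.kTCd, True),
            (f"gactive_{gid}", g.copy_number * g.active_fraction, False),
        ):
            p = _check(m.createParameter(), f"parameter {pname}")
            p.setId(pname)
            p.setValue(val)
            p.setConstant(const)
        rr = _check(m.createRateRule(), f"rate rule gactive_{gid}")
        rr.setVariable(f"gactive_{gid}")
        rr.setMath(libsbml.parseL3Formula(
            f"kGac_{gid} * (GCN_{gid} - gactive_{gid}) - kGin_{gid} * gactive_{gid}"
        ))

        mrna = sanitize_id(model.mrna_species(g.gene))
        comp = sanitize_id(model.species[model.mrna_species(g.gene)].compartment)
        tars = model.tars_targeting(g.gene)
        act = " + ".join(
            _hill_term(sanitize_id(t.regulator), t.K_A, t.n_A)
            for t in tars if t.sign == ACTIVATOR
        )
        rep = " * ".join(
            f"(1 - {_hill_term(sanitize_id(t.regulator), t.K_A, t.n_A)})"
            for t in tars if t.sign != ACTIVATOR
        )
        formula = f"gactive_{gid} * kTCb_{gid} * nm_per_molecule_{comp}"
        if act:
            formula += f" * (1 + {act})"
        if rep:
            formula += f" * {rep}"

        rx = _check(m.createReaction(), f"transcription vTC_{gid}")
        rx.setId(f"vTC_{gid}")
        rx.setReversible(False)
        sr = rx.createProduct()
        sr.setSpecies(mrna)
        sr.setStoichiometry(1.0)
        sr.setConstant(True)
        for t in tars:
            mod = rx.createModifier()
            mod.setSpecies(sanitize_id(t.regulator))
        kl = _check(rx.createKineticLaw(), f"kinetic law vTC_{gid}")
        _set_formula(kl, formula, f"transcription {g.gene}")

        rx = _check(m.createReaction(), f"mRNA degradation vTCdeg_{gid}")
        rx.setId(f"vTCdeg_{gid}")
        rx.setReversible(False)
        sr = rx.createReactant()
        sr.setSpecies(mrna)
        sr.setStoichiometry(1.0)
        sr.setConstant(True)
        kl = _check(rx.createKineticLaw(), f"kinetic law vTCdeg_{gid}")
        _set_formula(kl, f"kTCd_{gid} * {mrna}", f"mRNA degradation {g.gene}")

    errors = validate_sbml(doc)
    if errors:
        raise SBMLExportError("SBML validation failed:\n" + "\n".join(errors))
    if idmap:
        log.info("identifier sanitization map: %s", idmap)
    if path is not None:
        libsbml.writeSBMLToFile(doc, str(path))
    return doc


def validate_sbml(doc: libsbml.SBMLDocument) -> list[str]:
    """Run libSBML consistency checks; return error-severity messages."""
    doc.checkConsistency()
    msgs = []
    for i in range(doc.getNumErrors()):
        e = doc.getError(i)
        if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            msgs.append(f"line {e.getLine()}: {e.getMessage().strip()}")
    return msgs


@dataclass
class SBMLSummary:
    """Counts and values extracted from an SBML document for round-trip checks."""

    n_compartments: int
    n_species: int
    n_reactions: int
    n_parameters: int  # global + local
    species_initial: dict[str, float] = field(default_factory=dict)
    parameter_values: dict[str, float] = field(default_factory=dict)


def summarize_sbml(source: str | Path | libsbml.SBMLDocument) -> SBMLSummary:
    if isinstance(source, libsbml.SBMLDocument):
        doc = source
    else:
        doc = libsbml.readSBMLFromFile(str(source))
        if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
            raise ValueError(f"cannot read SBML from {source}")
    m = doc.getModel()
    species_initial = {
        m.getSpecies(i).getId(): m.getSpecies(i).getInitialConcentration()
        for i in range(m.getNumSpecies())
    }
    params = {
        m.getParameter(i).getId(): m.getParameter(i).getValue()
        for i in range(m.getNumParameters())
    }
    n_local = 0
    for i in range(m.getNumReactions()):
        kl = m.getReaction(i).getKineticLaw()
        if kl is None:
            continue
        for j in range(kl.getNumLocalParameters()):
            lp = kl.getLocalParameter(j)
            params[f"{m.getReaction(i).getId()}.{lp.getId()}"] = lp.getValue()
            n_local += 1
    return SBMLSummary(
        n_compartments=m.getNumCompartments(),
        n_species=m.getNumSpecies(),
        n_reactions=m.getNumReactions(),
        n_parameters=m.getNumParameters() + n_local,
        species_initial=species_initial,
        parameter_values=params,
    )


def enlarge_sbml(
    doc: libsbml.SBMLDocument,
    new_species: list[tuple[str, str, float]] = (),
    new_reactions: list[tuple[str, str, str, dict]] = (),
    new_parameters: list[tuple[str, float]] = (),
    merge: bool = False,
) -> libsbml.SBMLDocument:
    """Enlarge any SBML document with user-defined lists of elements.

    ``new_species``: (id, compartment, initial nM); ``new_reactions``:
    (id, "A + B -> C" reaction string, kinetic formula, local parameter
    dict); ``new_parameters``: (id, value).  Identifier collisions raise
    unless ``merge`` is set, in which case the existing element is kept
    and the duplicate skipped.  A reaction referencing a species absent
    from both the document and ``new_species`` is an error naming it.
    Returns a modified clone; the input document is untouched.
    """
    out = doc.clone()
    m = out.getModel()
    existing_species = {m.getSpecies(i).getId() for i in range(m.getNumSpecies())}
    existing_params = {m.getParameter(i).getId() for i in range(m.getNumParameters())}
    existing_rxns = {m.getReaction(i).getId() for i in range(m.getNumReactions())}
    merged = 0

    for sid, comp, init in new_species:
        if sid in existing_species:
            if not merge:
                raise ValueError(f"species {sid} already present (pass merge=True to keep)")
            merged += 1
            continue
        if m.getCompartment(comp) is None:
            raise ValueError(f"species {sid}: unknown compartment {comp}")
        s = m.createSpecies()
        s.setId(sid)
        s.setCompartment(comp)
        s.setInitialConcentration(init)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        existing_species.add(sid)

    for pid, value in new_parameters:
        if pid in existing_params:
            if not merge:
                raise ValueError(f"parameter {pid} already present")
            merged += 1
            continue
        p = m.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        existing_params.add(pid)

    for rid, reaction, formula, params in new_reactions:
        if rid in existing_rxns:
            if not merge:
                raise ValueError(f"reaction {rid} already present")
            merged += 1
            continue
        reactants, products = parse_reaction(reaction)
        for _, name in reactants + products:
            if name not in existing_species:
                raise ValueError(f"reaction {rid} references missing species {name}")
        rx = m.createReaction()
        rx.setId(rid)
        rx.setReversible(False)
        for coef, name in reactants:
            sr = rx.createReactant()
            sr.setSpecies(name)
            sr.setStoichiometry(coef)
            sr.setConstant(True)
        for coef, name in products:
            sr = rx.createProduct()
            sr.setSpecies(name)
            sr.setStoichiometry(coef)
            sr.setConstant(True)
        kl = rx.createKineticLaw()
        for k, v in (params or {}).items():
            lp = kl.createLocalParameter()
            lp.setId(k)
            lp.setValue(v)
        _set_formula(kl, formula, f"reaction {rid}")
        existing_rxns.add(rid)

    errors = validate_sbml(out)
    if errors:
        raise SBMLExportError("enlarged SBML fails validation:\n" + "\n".join(errors))
    if merged:
        log.info("enlarge_sbml: %d duplicate elements merged (kept existing)", merged)
    return out
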