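"""Readers and writers: SBML level-3 FBC (via cobrapy) and a TSV dialect.

TSV model files have a header ``id  equation  gpr  role  subsystem`` with
equations written ``(1) A[c] + (2) B[c] <=> (1) C[c]``; ``=>`` marks an
irreversible reaction, ``<=>`` a reversible one, and either side may be
empty (exchange / sink reactions).  Compartments ride in square brackets.
Coefficients are serialized to 12 significant digits.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Dict, Optional, Tuple

from .gpr import parse_gpr
from .types import (
    BiochemDatabase,
    Media,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ROLE_BIOMASS,
    ROLE_EXCHANGE,
    ROLE_INTERNAL,
)

__all__ = [
    "read_model",
    "write_model",
    "read_database",
    "write_database",
    "read_media",
    "write_media",
    "read_biomass_table",
    "read_flux_table",
    "write_flux_table",
]

_TERM_RE = re.compile(r"^\(([^)]+)\)\s+(\S+?)\[(\w+)\]$")


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    return "tsv"


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def _parse_side(text: str, rxn_id: str) -> Dict[Tuple[str, str], float]:
    out: Dict[Tuple[str, str], float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split(" + "):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise ModelValidationError(
                f"reaction {rxn_id!r}: cannot parse term {term.strip()!r}"
            )
        coef_s, met, comp = m.groups()
        try:
            coef = float(coef_s)
        except ValueError as exc:
            raise ModelValidationError(
                f"reaction {rxn_id!r}: bad coefficient {coef_s!r}"
            ) from exc
        key = (met, comp)
        out[key] = out.get(key, 0.0) + coef
    return out


def parse_equation(
    equation: str, rxn_id: str
) -> Tuple[Dict[Tuple[str, str], float], bool]:
    """Parse an equation string -> ({(met, compartment): signed coef}, reversible)."""
    if "<=>" in equation:
        lhs, rhs = equation.split("<=>", 1)
        reversible = True
    elif "=>" in equation:
        lhs, rhs = equation.split("=>", 1)
        reversible = False
    else:
        raise ModelValidationError(
            f"reaction {rxn_id!r}: equation lacks '=>' or '<=>'"
        )
    stoich: Dict[Tuple[str, str], float] = {}
    for key, coef in _parse_side(lhs, rxn_id).items():
        stoich[key] = stoich.get(key, 0.0) - coef
    for key, coef in _parse_side(rhs, rxn_id).items():
        stoich[key] = stoich.get(key, 0.0) + coef
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelValidationError(f"reaction {rxn_id!r}: empty equation")
    return stoich, reversible


def format_equation(rxn: Reaction, model: MetabolicModel) -> str:
    lhs, rhs = [], []
    for mid, coef in rxn.stoichiometry.items():
        comp = model.metabolites[mid].compartment
        term = f"({abs(coef):.12g}) {mid}[{comp}]"
        (lhs if coef < 0 else rhs).append(term)
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _read_tsv_rows(path):
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader), reader.fieldnames or []


def _model_from_rows(rows, model_id: str) -> MetabolicModel:
    model = MetabolicModel(model_id)
    for row in rows:
        rid = (row.get("id") or "").strip()
        if not rid:
            continue
        stoich_keys, reversible = parse_equation(row["equation"], rid)
        for met, comp in stoich_keys:
            if met not in model.metabolites:
                model.add_metabolite(Metabolite(id=met, compartment=comp))
            elif model.metabolites[met].compartment != comp:
                raise ModelValidationError(
                    f"metabolite {met!r} appears in two compartments"
                )
        role = (row.get("role") or ROLE_INTERNAL).strip() or ROLE_INTERNAL
        subsystem = (row.get("subsystem") or "").strip() or None
        rxn = Reaction(
            id=rid,
            stoichiometry={met: coef for (met, _c), coef in stoich_keys.items()},
            reversible=reversible,
            gpr=parse_gpr(row.get("gpr") or ""),
            role=role,
            subsystem=subsystem,
        )
        model.add_reaction(rxn)
    model.validate()
    return model


def _read_model_tsv(path) -> MetabolicModel:
    rows, fields = _read_tsv_rows(path)
    for col in ("id", "equation"):
        if col not in fields:
            raise ModelValidationError(f"model TSV {path} lacks column {col!r}")
    return _model_from_rows(rows, Path(path).stem)


def _write_model_tsv(model: MetabolicModel, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "equation", "gpr", "role", "subsystem"])
        for rxn in model.reactions.values():
            writer.writerow(
                [
                    rxn.id,
                    format_equation(rxn, model),
                    rxn.gpr.to_string() if rxn.gpr else "",
                    rxn.role,
                    rxn.subsystem or "",
                ]
            )


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------


def _read_model_sbml(path) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    model = MetabolicModel(cm.id or Path(path).stem)
    for met in cm.metabolites:
        model.add_metabolite(
            Metabolite(
                id=met.id,
                name=met.name or met.id,
                compartment=met.compartment or "c",
                formula=met.formula or None,
            )
        )
    for rxn in cm.reactions:
        role = ROLE_INTERNAL
        if len(rxn.metabolites) == 1:
            role = ROLE_EXCHANGE
        if rxn.objective_coefficient:
            role = ROLE_BIOMASS
        model.add_reaction(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
                reversible=rxn.lower_bound < 0,
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                gpr=parse_gpr(rxn.gene_reaction_rule),
                role=role,
                subsystem=rxn.subsystem or None,
            )
        )
    model.validate()
    return model


def _write_model_sbml(model: MetabolicModel, path) -> None:
    import cobra
    import cobra.io

    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [
            cobra.Metabolite(
                id=met.id,
                name=met.name,
                compartment=met.compartment,
                formula=met.formula,
            )
            for met in model.metabolites.values()
        ]
    )
    crxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(
            id=rxn.id,
            lower_bound=rxn.lower_bound if rxn.reversible else max(0.0, rxn.lower_bound),
            upper_bound=rxn.upper_bound,
        )
        crxns.append((cr, rxn))
    cm.add_reactions([cr for cr, _ in crxns])
    for cr, rxn in crxns:
        cr.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()}
        )
        if rxn.gpr is not None:
            cr.gene_reaction_rule = rxn.gpr.to_string()
        if rxn.subsystem:
            cr.subsystem = rxn.subsystem
    if model.biomass_id is not None:
        cm.objective = model.biomass_id
    cobra.io.write_sbml_model(cm, str(path))


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from SBML (level 3 FBC) or the TSV dialect."""
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        return _read_model_sbml(path)
    if fmt == "tsv":
        return _read_model_tsv(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    model.validate()
    if fmt == "sbml":
        _write_model_sbml(model, path)
    elif fmt == "tsv":
        _write_model_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def read_database(path) -> BiochemDatabase:
    """Candidate-reaction TSV: ``id equation gpr penalty`` (penalty defaults 1)."""
    rows, fields = _read_tsv_rows(path)
    db = BiochemDatabase()
    holder = MetabolicModel("db_holder")
    for row in rows:
        rid = (row.get("id") or "").strip()
        if not rid:
            continue
        stoich_keys, reversible = parse_equation(row["equation"], rid)
        for met, comp in stoich_keys:
            if met not in holder.metabolites:
                holder.add_metabolite(Metabolite(id=met, compartment=comp))
        rxn = Reaction(
            id=rid,
            stoichiometry={met: coef for (met, _c), coef in stoich_keys.items()},
            reversible=reversible,
            gpr=parse_gpr(row.get("gpr") or ""),
            source="database",
        )
        penalty = float(row.get("penalty") or 1.0)
        db.add(rxn, penalty)
    return db


def write_database(db: BiochemDatabase, path) -> None:
    holder = MetabolicModel("db_holder")
    for rxn in db.reactions.values():
        for mid in rxn.stoichiometry:
            if mid not in holder.metabolites:
                holder.add_metabolite(Metabolite(id=mid, compartment="c"))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "equation", "gpr", "penalty"])
        for rid, rxn in db.reactions.items():
            writer.writerow(
                [
                    rid,
                    format_equation(rxn, holder),
                    rxn.gpr.to_string() if rxn.gpr else "",
                    f"{db.penalties[rid]:.6g}",
                ]
            )


def read_media(path, default_cap: float = 100.0) -> Media:
    rows, fields = _read_tsv_rows(path)
    if "metabolite_id" not in fields:
        raise ModelValidationError(f"media TSV {path} lacks column 'metabolite_id'")
    limits = {
        row["metabolite_id"].strip(): float(row.get("max_uptake") or 0.0)
        for row in rows
        if (row.get("metabolite_id") or "").strip()
    }
    return Media(uptake_limits=limits, default_cap=default_cap)


def write_media(media: Media, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metabolite_id", "max_uptake"])
        for mid, lim in media.uptake_limits.items():
            writer.writerow([mid, f"{lim:.6g}"])


def read_biomass_table(path) -> Dict[str, float]:
    """Biomass coefficient TSV: ``metabolite_id  coefficient`` (negative = consumed)."""
    rows, fields = _read_tsv_rows(path)
    return {
        row["metabolite_id"].strip(): float(row["coefficient"])
        for row in rows
        if (row.get("metabolite_id") or "").strip()
    }


def read_flux_table(path) -> Dict[str, float]:
    """Measured-flux TSV: ``reaction_id  flux``."""
    rows, fields = _read_tsv_rows(path)
    return {
        row["reaction_id"].strip(): float(row["flux"])
        for row in rows
        if (row.get("reaction_id") or "").strip()
    }


def write_flux_table(fluxes: Dict[str, float], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["reaction_id", "flux"])
        for rid, v in fluxes.items():
            writer.writerow([rid, f"{v:.6g}"])
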