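"""Model input/output and structural curation.

Reads genome-scale models from BIGG-style JSON (natively) or SBML (through
cobrapy) into :class:`~sensnet.model.MetabolicModel`, writes them back as
JSON, and curates them: a feasibility check of biomass production with all
uptakes open, followed by removal of structurally blocked reactions found by
flux variability analysis (FVA), with a sanity check that the biomass
optimum is unchanged by the reduction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "load_model",
    "save_model",
    "curate_model",
    "CurationReport",
    "fva",
    "maximize_biomass",
]

_DEFAULT_BOUND = 1000.0
_GENE_TOKEN = re.compile(r"[^\s()]+")


class ModelFormatError(ValueError):
    """Raised when an input file does not parse under the named standard."""


def _genes_from_rule(rule: str | None) -> list[str]:
    if not rule:
        return []
    seen: list[str] = []
    for tok in _GENE_TOKEN.findall(rule):
        if tok.lower() in ("and", "or"):
            continue
        if tok not in seen:
            seen.append(tok)
    return seen


def _ec_from_annotation(annotation: dict | None) -> list[str]:
    if not annotation:
        return []
    for key in ("ec-code", "ec_code", "EC", "ec"):
        if key in annotation:
            val = annotation[key]
            return [val] if isinstance(val, str) else list(val)
    return []


def load_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Load a metabolic model from a BIGG-style JSON or SBML file.

    Reaction order is preserved from the file.  Reversibility is taken from
    the declared flux bounds (lower bound < 0).  The biomass reaction is the
    one with a nonzero objective coefficient, falling back to an id match on
    'biomass'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        return _load_json(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown format {format!r}; expected 'json' or 'sbml'")


def _load_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    for section in ("metabolites", "reactions"):
        if section not in doc:
            raise ModelFormatError(f"{path}: missing {section!r} section")

    metabolites = []
    raw_to_canonical: dict[str, str] = {}
    for m in doc["metabolites"]:
        if "id" not in m:
            raise ModelFormatError(f"{path}: metabolite without id")
        met = Metabolite(
            id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "")
        )
        metabolites.append(met)
        raw_to_canonical[m["id"]] = met.canonical_id

    reactions = []
    biomass = None
    for r in doc["reactions"]:
        if "id" not in r or "metabolites" not in r:
            raise ModelFormatError(f"{path}: malformed reaction entry {r.get('id')!r}")
        stoich = {}
        for raw, coef in r["metabolites"].items():
            if raw not in raw_to_canonical:
                raise ModelFormatError(
                    f"{path}: reaction {r['id']!r} references undeclared "
                    f"metabolite {raw!r}"
                )
            stoich[raw_to_canonical[raw]] = float(coef)
        lb = float(r.get("lower_bound", 0.0))
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry=stoich,
                reversible=lb < 0,
                subsystem=r.get("subsystem") or None,
                ec_numbers=_ec_from_annotation(r.get("annotation")),
                genes=_genes_from_rule(r.get("gene_reaction_rule")),
            )
        )
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            biomass = r["id"]
    if biomass is None:
        for r in reactions:
            if "biomass" in r.id.lower():
                biomass = r.id
                break
    if not metabolites or not reactions:
        raise ModelFormatError(f"{path}: empty model")
    return MetabolicModel(
        id=doc.get("id", path.stem),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction=biomass,
    )


def _load_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various parser errors
        raise ModelFormatError(f"{path}: SBML parse failure ({exc})") from exc

    metabolites = []
    raw_to_canonical = {}
    for m in cm.metabolites:
        met = Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        metabolites.append(met)
        raw_to_canonical[m.id] = met.canonical_id

    reactions = []
    biomass = None
    for r in cm.reactions:
        stoich = {raw_to_canonical[m.id]: float(c) for m, c in r.metabolites.items()}
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                reversible=r.lower_bound < 0,
                subsystem=r.subsystem or None,
                ec_numbers=_ec_from_annotation(r.annotation),
                genes=[g.id for g in r.genes],
            )
        )
        if r.objective_coefficient:
            biomass = r.id
    if biomass is None:
        for r in reactions:
            if "biomass" in r.id.lower():
                biomass = r.id
                break
    if not metabolites or not reactions:
        raise ModelFormatError(f"{path}: empty model")
    return MetabolicModel(
        id=cm.id or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction=biomass,
    )


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write ``model`` as BIGG-style JSON (exact round-trip of N)."""
    canonical_to_raw = {m.canonical_id: m.id for m in model.metabolites}
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [],
        "genes": sorted({g for r in model.reactions for g in r.genes}),
    }
    for r in model.reactions:
        entry = {
            "id": r.id,
            "metabolites": {
                canonical_to_raw[met]: coef for met, coef in r.stoichiometry.items()
            },
            "lower_bound": -_DEFAULT_BOUND if r.reversible else 0.0,
            "upper_bound": _DEFAULT_BOUND,
            "gene_reaction_rule": " or ".join(r.genes),
            "subsystem": r.subsystem or "",
        }
        if r.ec_numbers:
            entry["annotation"] = {"ec-code": list(r.ec_numbers)}
        if r.id == model.biomass_reaction:
            entry["objective_coefficient"] = 1.0
        doc["reactions"].append(entry)
    Path(path).write_text(json.dumps(doc, indent=1))


# -- linear programming helpers ------------------------------------------


def _bounds(model: MetabolicModel, open_uptake: bool) -> list[tuple[float, float]]:
    """Flux bounds from declared reversibility; optionally open all
    exchange lower bounds so every exchanged metabolite can be taken up."""
    bounds = []
    for r in model.reactions:
        lb = -_DEFAULT_BOUND if r.reversible else 0.0
        if open_uptake and r.is_exchange:
            lb = -_DEFAULT_BOUND
        bounds.append((lb, _DEFAULT_BOUND))
    return bounds


def maximize_biomass(model: MetabolicModel) -> float:
    """Maximal biomass flux at steady state with all uptakes open."""
    if model.biomass_reaction is None:
        raise ValueError(f"model {model.id!r} has no biomass reaction")
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_index(model.biomass_reaction)] = -1.0
    res = linprog(
        c, A_eq=model.N, b_eq=np.zeros(model.N.shape[0]),
        bounds=_bounds(model, open_uptake=True), method="highs",
    )
    if not res.success:
        raise RuntimeError(f"biomass LP failed for {model.id!r}: {res.message}")
    return -res.fun


def fva(model: MetabolicModel) -> np.ndarray:
    """Flux variability analysis: (n_reactions, 2) array of min/max flux."""
    N = model.N
    bounds = _bounds(model, open_uptake=True)
    b_eq = np.zeros(N.shape[0])
    n = N.shape[1]
    out = np.zeros((n, 2))
    for j in range(n):
        c = np.zeros(n)
        for col, sign in ((0, 1.0), (1, -1.0)):
            c[j] = sign
            res = linprog(c, A_eq=N, b_eq=b_eq, bounds=bounds, method="highs")
            if not res.success:
                raise RuntimeError(f"FVA LP failed on {model.reactions[j].id!r}")
            out[j, col] = sign * res.fun
    return out


@dataclass
class CurationReport:
    model_id: str
    feasible: bool
    biomass_before: float = float("nan")
    biomass_after: float = float("nan")
    removed: list[str] = field(default_factory=list)
    accepted: bool = False
    fva_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["reaction\tstatus\tfva_min\tfva_max"]
        removed = set(self.removed)
        for rid, (lo, hi) in self.fva_ranges.items():
            status = "removed" if rid in removed else "kept"
            lines.append(f"{rid}\t{status}\t{lo:.6g}\t{hi:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")


def curate_model(
    model: MetabolicModel, lp_tolerance: float = 1e-9
) -> tuple[MetabolicModel, CurationReport]:
    """Remove structurally blocked reactions, guarded by a biomass check.

    Steps: (1) verify biomass carries strictly positive flux with uptake of
    every exchanged metabolite allowed; (2) FVA with the same open bounds,
    removing reactions whose min and max flux are both zero within
    ``lp_tolerance``; (3) verify the reduced model's biomass optimum equals
    the original's — if not, the original model is returned and the report
    flags the reduction as rejected.
    """
    report = CurationReport(model_id=model.id, feasible=False)
    biomass_before = maximize_biomass(model)
    report.biomass_before = biomass_before
    if biomass_before <= lp_tolerance:
        return model, report  # rejected: biomass infeasible
    report.feasible = True

    ranges = fva(model)
    report.fva_ranges = {
        r.id: (float(lo), float(hi))
        for r, (lo, hi) in zip(model.reactions, ranges)
    }
    blocked = [
        r.id
        for r, (lo, hi) in zip(model.reactions, ranges)
        if abs(lo) <= lp_tolerance and abs(hi) <= lp_tolerance
    ]
    report.removed = blocked
    if not blocked:
        report.accepted = True
        report.biomass_after = biomass_before
        return model, report

    keep = [r for r in model.reactions if r.id not in set(blocked)]
    used_mets = {met for r in keep for met in r.stoichiometry}
    reduced = MetabolicModel(
        id=model.id,
        metabolites=[m for m in model.metabolites if m.canonical_id in used_mets],
        reactions=keep,
        biomass_reaction=model.biomass_reaction,
    )
    biomass_after = maximize_biomass(reduced)
    report.biomass_after = biomass_after
    tol = max(lp_tolerance, 1e-6 * max(1.0, abs(biomass_before)))
    if abs(biomass_after - biomass_before) > tol:
        report.accepted = False
        report.removed = []
        return model, report
    report.accepted = True
    return reduced, report
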