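"""Lightweight constraint-based metabolic model container and I/O.

A :class:`MetabolicModel` is a plain stoichiometric network: metabolites,
reactions with bounds, one biomass objective, and exchange flags.  Models can
be read from SBML (via :mod:`cobra`) or from a simple TSV dialect with one
reaction per line::

    reaction_id  equation            lower_bound  upper_bound  is_exchange  is_objective
    EX_A         -> A                0            10           1            0
    r1           A -> B              0            10           0            0
    bio          B ->                0            1000         0            1

Equations use ``A + 2 B -> C`` syntax; an empty side denotes a boundary
(exchange) reaction.  ``<->`` is accepted as an arrow as well — directionality
is carried by the bounds, not the arrow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

__all__ = [
    "Reaction",
    "MetabolicModel",
    "ModelFormatError",
    "read_model",
    "write_model_tsv",
    "write_model_sbml",
    "to_cobra",
    "from_cobra",
]


class ModelFormatError(ValueError):
    """Raised when a model file violates the format contract."""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelFormatError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds and a single biomass objective."""

    model_id: str
    metabolites: list[str]
    reactions: list[Reaction]
    objective_reaction: str
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelFormatError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
        declared = set(self.metabolites)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - declared
            if unknown:
                raise ModelFormatError(
                    f"reaction {rxn.id!r} references undeclared metabolite(s) "
                    f"{sorted(unknown)}"
                )
        if self.objective_reaction not in seen:
            raise ModelFormatError(
                f"objective reaction {self.objective_reaction!r} not found in model "
                f"{self.model_id!r}"
            )

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with shape (n_metabolites, n_reactions)."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, stoich: dict[str, float], sign: float, rid: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ModelFormatError(f"reaction {rid!r}: empty term in equation")
        m = _TERM_RE.match(term)
        if m is None:
            raise ModelFormatError(f"reaction {rid!r}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def parse_equation(equation: str, rid: str = "?") -> dict[str, float]:
    """Parse ``A + 2 B -> C`` into a stoichiometry dict (reactants negative)."""
    for arrow in ("<->", "<=>", "->", "=>"):
        if arrow in equation:
            lhs, rhs = equation.split(arrow, 1)
            break
    else:
        raise ModelFormatError(f"reaction {rid!r}: equation {equation!r} has no arrow")
    stoich: dict[str, float] = {}
    _parse_side(lhs, stoich, -1.0, rid)
    _parse_side(rhs, stoich, +1.0, rid)
    # cancelled species (catalytic appearance on both sides) are dropped
    return {m: c for m, c in stoich.items() if c != 0.0}


_TSV_COLUMNS = [
    "reaction_id",
    "equation",
    "lower_bound",
    "upper_bound",
    "is_exchange",
    "is_objective",
]


def _read_model_tsv(path: Path) -> MetabolicModel:
    lines = path.read_text().splitlines()
    if not lines:
        raise ModelFormatError(f"{path}: empty model file")
    header = [h.strip() for h in lines[0].split("\t")]
    if header != _TSV_COLUMNS:
        raise ModelFormatError(
            f"{path}: expected header {_TSV_COLUMNS}, found {header}"
        )
    reactions: list[Reaction] = []
    objective: str | None = None
    metabolites: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != len(_TSV_COLUMNS):
            raise ModelFormatError(
                f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} fields, found {len(parts)}"
            )
        rid, equation, lb, ub, is_ex, is_obj = parts
        stoich = parse_equation(equation, rid)
        metabolites.update(stoich)
        try:
            rxn = Reaction(rid, stoich, float(lb), float(ub), bool(int(is_ex)))
        except ModelFormatError as err:
            raise ModelFormatError(f"{path}:{lineno}: {err}") from err
        reactions.append(rxn)
        if int(is_obj):
            if objective is not None:
                raise ModelFormatError(f"{path}:{lineno}: multiple objective reactions")
            objective = rid
    if objective is None:
        raise ModelFormatError(f"{path}: no objective reaction flagged")
    return MetabolicModel(
        model_id=path.stem,
        metabolites=sorted(metabolites),
        reactions=reactions,
        objective_reaction=objective,
    )


def _format_equation(stoich: dict[str, float]) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        terms = []
        for met, coef in items:
            terms.append(met if coef == 1.0 else f"{coef:g} {met}")
        return " + ".join(terms)

    lhs = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    rhs = [(m, c) for m, c in sorted(stoich.items()) if c > 0]
    return f"{side(lhs)} -> {side(rhs)}".strip()


def write_model_tsv(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    out = ["\t".join(_TSV_COLUMNS)]
    for rxn in model.reactions:
        out.append(
            "\t".join(
                [
                    rxn.id,
                    _format_equation(rxn.stoichiometry),
                    f"{rxn.lower_bound:g}",
                    f"{rxn.upper_bound:g}",
                    str(int(rxn.is_exchange)),
                    str(int(rxn.id == model.objective_reaction)),
                ]
            )
        )
    path.write_text("\n".join(out) + "\n")


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (used for SBML I/O and oracle cross-checks)."""
    import cobra

    cm = cobra.Model(model.model_id)
    mets = {
        m: cobra.Metabolite(m, compartment=model.compartments.get(m, "c"))
        for m in model.metabolites
    }
    rxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rxn in model.reactions:
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[m]: c for m, c in rxn.stoichiometry.items()}
        )
    cm.objective = model.objective_reaction
    return cm


def from_cobra(cm, model_id: str | None = None) -> MetabolicModel:
    """Convert a cobra.Model; exchange = single-metabolite boundary reaction."""
    reactions = []
    objective = None
    for cr in cm.reactions:
        stoich = {m.id: float(c) for m, c in cr.metabolites.items()}
        is_exchange = len(stoich) == 1 and cr.boundary
        if cr.objective_coefficient:
            if objective is not None:
                raise ModelFormatError(f"model {cm.id!r}: multiple objective reactions")
            objective = cr.id
        reactions.append(
            Reaction(cr.id, stoich, float(cr.lower_bound), float(cr.upper_bound), is_exchange)
        )
    if objective is None:
        raise ModelFormatError(f"model {cm.id!r}: no objective reaction")
    return MetabolicModel(
        model_id=model_id or cm.id,
        metabolites=sorted(m.id for m in cm.metabolites),
        reactions=reactions,
        objective_reaction=objective,
        compartments={m.id: m.compartment or "c" for m in cm.metabolites},
    )


def write_model_sbml(model: MetabolicModel, path: str | Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def read_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Read a model from SBML (``.xml``/``.sbml``) or the TSV dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tsv"
    if dialect == "tsv":
        return _read_model_tsv(path)
    if dialect == "sbml":
        from cobra.io import read_sbml_model

        return from_cobra(read_sbml_model(str(path)), model_id=path.stem)
    raise ValueError(f"unknown model dialect {dialect!r}")
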