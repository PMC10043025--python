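"""Core data structures for metabolic networks.

A metabolic network is represented by its stoichiometric matrix ``N``
(metabolites x reactions) together with per-reaction metadata: reversibility,
exchange status, subsystem label, EC numbers and associated genes.  Reactions
are matched *across* models by their biochemical formula, encoded as a
:class:`ReactionKey` that is invariant to metabolite ordering and to the
direction in which the reaction happens to be written.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionKey",
    "MetabolicModel",
    "reaction_key",
    "common_reactions",
]


@dataclass(frozen=True)
class Metabolite:
    """A metabolite in one compartment of one model.

    ``canonical_id`` is the namespace-resolved identity used for cross-model
    matching; the compartment is part of it (``glc__D[c]`` differs from
    ``glc__D[e]``), so transport steps stay distinct from conversions.
    """

    id: str
    name: str = ""
    compartment: str = ""

    @property
    def canonical_id(self) -> str:
        if self.compartment:
            base = self.id
            suffix = "_" + self.compartment
            if base.endswith(suffix):
                base = base[: -len(suffix)]
            return f"{base}[{self.compartment}]"
        return self.id


@dataclass
class Reaction:
    """A reaction as a signed stoichiometry over canonical metabolite ids.

    Negative coefficients are substrates, positive are products, in the
    direction the model writes the reaction.  Exchange pseudo-reactions touch
    exactly one metabolite.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    subsystem: str | None = None
    ec_numbers: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stoichiometry = {
            m: float(c) for m, c in self.stoichiometry.items() if c != 0
        }
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass(frozen=True)
class ReactionKey:
    """Direction- and order-invariant identity of a reaction formula.

    ``canonical_form`` is the sorted tuple of (canonical metabolite id,
    coefficient) pairs in the canonical orientation; ``orientation_sign`` is
    +1 if the model writes the reaction in that orientation and -1 if it
    writes it reversed.  Two reactions share a ``canonical_form`` iff their
    stoichiometries are identical up to overall sign.
    """

    canonical_form: tuple[tuple[str, float], ...]
    orientation_sign: int = 1

    def __eq__(self, other: object) -> bool:  # identity ignores orientation
        if not isinstance(other, ReactionKey):
            return NotImplemented
        return self.canonical_form == other.canonical_form

    def __hash__(self) -> int:
        return hash(self.canonical_form)


def reaction_key(reaction: Reaction) -> ReactionKey:
    """Canonical cross-model identity of ``reaction``.

    The canonical orientation is the one whose sorted substrate-id tuple is
    lexicographically smaller; ties fall back to the full signed form.  The
    rule uses only metabolite ids, so it is deterministic and identical in
    every model that shares the metabolite namespace.
    """
    items = sorted(reaction.stoichiometry.items())
    forward = tuple((m, float(c)) for m, c in items)
    backward = tuple((m, -float(c)) for m, c in items)

    def substrate_side(form: tuple[tuple[str, float], ...]) -> tuple[str, ...]:
        return tuple(m for m, c in form if c < 0)

    sub_f, sub_b = substrate_side(forward), substrate_side(backward)
    if (sub_f, forward) <= (sub_b, backward):
        return ReactionKey(canonical_form=forward, orientation_sign=1)
    return ReactionKey(canonical_form=backward, orientation_sign=-1)


@dataclass
class MetabolicModel:
    """One species' metabolic network.

    Holds the ordered metabolite and reaction lists, the stoichiometric
    matrix ``N`` (built lazily from reaction stoichiometries), the optional
    biomass reaction and the gene -> reactions map derived from per-reaction
    gene annotations.
    """

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction: str | None = None

    def __post_init__(self) -> None:
        self._validate()
        self._N: np.ndarray | None = None
        self._keys: list[ReactionKey] | None = None

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ValueError(f"model {self.id!r}: duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError(f"model {self.id!r}: duplicate reaction ids")
        if not self.metabolites or not self.reactions:
            raise ValueError(f"model {self.id!r} is empty")
        known = {m.canonical_id for m in self.metabolites}
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValueError(
                    f"model {self.id!r}: reaction {r.id!r} references "
                    f"undeclared metabolites {sorted(missing)}"
                )
        if self.biomass_reaction is not None and self.biomass_reaction not in set(
            rxn_ids
        ):
            raise ValueError(
                f"model {self.id!r}: biomass reaction "
                f"{self.biomass_reaction!r} not in model"
            )

    # -- derived views -----------------------------------------------------

    @property
    def N(self) -> np.ndarray:
        """Stoichiometric matrix, metabolites x reactions."""
        if self._N is None:
            met_index = {m.canonical_id: i for i, m in enumerate(self.metabolites)}
            N = np.zeros((len(self.metabolites), len(self.reactions)))
            for j, r in enumerate(self.reactions):
                for met, coef in r.stoichiometry.items():
                    N[met_index[met], j] = coef
            self._N = N
        return self._N

    @property
    def reaction_keys(self) -> list[ReactionKey]:
        if self._keys is None:
            self._keys = [reaction_key(r) for r in self.reactions]
        return self._keys

    @property
    def gene_to_reactions(self) -> dict[str, set[str]]:
        mapping: dict[str, set[str]] = {}
        for r in self.reactions:
            for g in r.genes:
                mapping.setdefault(g, set()).add(r.id)
        return mapping

    def reaction_index(self, reaction_id: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == reaction_id:
                return i
        raise KeyError(reaction_id)

    def key_to_index(self) -> dict[ReactionKey, int]:
        """Map each distinct reaction key to one reaction index.

        Duplicate identical formulas within one model collapse to the first
        occurrence (logged); cross-model matching then sees one
        representative per formula.
        """
        mapping: dict[ReactionKey, int] = {}
        for i, key in enumerate(self.reaction_keys):
            if key in mapping:
                logger.info(
                    "model %s: reaction %s duplicates formula of %s; "
                    "collapsed for cross-model matching",
                    self.id,
                    self.reactions[i].id,
                    self.reactions[mapping[key]].id,
                )
            else:
                mapping[key] = i
        return mapping

    def subsystems(self) -> dict[str, list[ReactionKey]]:
        """Subsystem label -> reaction keys, 'unassigned' pooling the rest."""
        out: dict[str, list[ReactionKey]] = {}
        for r, key in zip(self.reactions, self.reaction_keys):
            label = r.subsystem if r.subsystem else "unassigned"
            out.setdefault(label, []).append(key)
        return out


def common_reactions(l: MetabolicModel, m: MetabolicModel) -> set[ReactionKey]:
    """Reactions with identical biochemical formula in both models.

    Matching is by canonical form, so shared reactions written in opposite
    directions still count as common.  Zero shared metabolites usually means
    the two models use different namespaces; that returns an empty set with
    a warning rather than an error.
    """
    keys_l = set(l.key_to_index())
    keys_m = set(m.key_to_index())
    shared = keys_l & keys_m
    if not shared:
        mets_l = {met.canonical_id for met in l.metabolites}
        mets_m = {met.canonical_id for met in m.metabolites}
        if not mets_l & mets_m:
            warnings.warn(
                f"models {l.id!r} and {m.id!r} share no metabolites; "
                "are they in the same namespace?",
                stacklevel=2,
            )
    return shared
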