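"""Synthetic metabolic networks with known ground truth.

Real genome-scale models are large downloads with noisy annotations; the
generators here emit small, fully controlled stand-ins: single networks with
a guaranteed nontrivial null space, model pairs derived by known divergence
operations (reaction deletion, direction flips), collections with planted
conserved/variable subsystems, and feature tables with planted regression
effects.  All ground truth (common sets, true mappings, planted
coefficients) is emitted alongside the data and is exactly consistent with
it by construction.

Stoichiometric coefficients are drawn from {1, 2} and internal reactions
touch 2-4 metabolites, which is typical of curated metabolic
reconstructions.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Any

import numpy as np

from .comparative import FeatureTable
from .model import MetabolicModel, Metabolite, Reaction, reaction_key

__all__ = [
    "make_network",
    "make_pair",
    "make_collection",
    "make_feature_study",
    "Collection",
]


def _metabolite(mid: str) -> Metabolite:
    return Metabolite(id=f"{mid}_c", name=mid, compartment="c")


def make_network(
    seed: int,
    n_metabolites: int = 10,
    n_reactions: int = 16,
    reversibility_fraction: float = 0.3,
    exchange_fraction: float = 0.15,
    with_biomass: bool = False,
    model_id: str | None = None,
) -> MetabolicModel:
    """Random connected network with exchanges and a nontrivial null space.

    A linear chain through all metabolites plus an uptake and a secretion
    exchange guarantees connectivity and at least one unblocked flux route;
    the remaining reactions are random sparse conversions.  Requires
    ``n_reactions > n_metabolites`` so the null space is nonempty.
    """
    rng = np.random.default_rng(seed)
    m = n_metabolites
    if n_reactions <= m:
        raise ValueError(
            "n_reactions must exceed n_metabolites for a nontrivial null space"
        )
    met_names = [f"M{i}" for i in range(m)]
    metabolites = [_metabolite(name) for name in met_names]
    canon = {name: met.canonical_id for name, met in zip(met_names, metabolites)}

    reactions: list[Reaction] = []
    # connectivity backbone: M0 -> M1 -> ... -> M_{m-1}
    for i in range(m - 1):
        reactions.append(
            Reaction(
                id=f"R_chain_{i}",
                stoichiometry={canon[met_names[i]]: -1.0,
                               canon[met_names[i + 1]]: 1.0},
            )
        )
    # boundary exchanges: uptake of M0, secretion of the chain end
    n_exchanges = max(2, round(exchange_fraction * n_reactions))
    exchange_mets = [met_names[0], met_names[-1]]
    extra = [x for x in met_names[1:-1]]
    rng.shuffle(extra)
    exchange_mets += extra[: n_exchanges - 2]
    for name in exchange_mets:
        reactions.append(
            Reaction(
                id=f"EX_{name}",
                stoichiometry={canon[name]: -1.0},
                reversible=True,
            )
        )
    biomass_id = None
    if with_biomass:
        subs = [met_names[-1]] + list(
            rng.choice(met_names[1:-1], size=min(2, m - 2), replace=False)
        )
        biomass_id = "BIOMASS"
        reactions.append(
            Reaction(
                id=biomass_id,
                stoichiometry={canon[s]: -1.0 for s in subs},
            )
        )
    # random sparse conversions fill the remaining columns
    while len(reactions) < n_reactions:
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(m, size=n_sub + n_prod, replace=False)
        stoich: dict[str, float] = {}
        for p in picks[:n_sub]:
            stoich[canon[met_names[p]]] = -float(rng.choice([1, 2]))
        for p in picks[n_sub:]:
            stoich[canon[met_names[p]]] = float(rng.choice([1, 2]))
        reactions.append(
            Reaction(id=f"R_rand_{len(reactions)}", stoichiometry=stoich)
        )
    # reversibility flags on internal reactions
    internal = [r for r in reactions if not r.is_exchange and r.id != biomass_id]
    n_rev = round(reversibility_fraction * len(internal))
    for idx in rng.choice(len(internal), size=n_rev, replace=False):
        internal[idx].reversible = True
    return MetabolicModel(
        id=model_id or f"synth{seed}",
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction=biomass_id,
    )


def make_pair(
    base: MetabolicModel,
    n_delete: int = 0,
    flip_fraction: float = 0.0,
    seed: int = 0,
    copy_id: str | None = None,
) -> tuple[MetabolicModel, MetabolicModel, dict[str, Any]]:
    """Derive a diverged copy of ``base`` with known ground truth.

    Divergence operations: delete ``n_delete`` random non-exchange
    reactions (a randomly reduced version of the model) and flip the
    written direction of a random ``flip_fraction`` of the survivors
    (which changes nothing functionally and must be absorbed by sign
    reconciliation).  The returned truth records the common reaction keys
    and the identity mapping between them.
    """
    rng = np.random.default_rng(seed)
    deletable = [r.id for r in base.reactions if not r.is_exchange
                 and r.id != base.biomass_reaction]
    if n_delete > len(deletable):
        raise ValueError("cannot delete more reactions than the model has")
    deleted = set(
        rng.choice(deletable, size=n_delete, replace=False).tolist()
        if n_delete
        else []
    )
    survivors = [r for r in base.reactions if r.id not in deleted]
    if len(survivors) < 3:
        raise ValueError("divergence leaves fewer than 3 common reactions")
    n_flip = round(flip_fraction * len(survivors))
    flip = set(
        rng.choice([r.id for r in survivors], size=n_flip, replace=False).tolist()
        if n_flip
        else []
    )
    copy_reactions = []
    for r in survivors:
        stoich = dict(r.stoichiometry)
        if r.id in flip:
            stoich = {k: -v for k, v in stoich.items()}
        copy_reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                reversible=r.reversible,
                subsystem=r.subsystem,
                ec_numbers=list(r.ec_numbers),
                genes=list(r.genes),
            )
        )
    used = {met for r in copy_reactions for met in r.stoichiometry}
    copy = MetabolicModel(
        id=copy_id or f"{base.id}_div",
        metabolites=[m for m in base.metabolites if m.canonical_id in used],
        reactions=copy_reactions,
        biomass_reaction=(
            base.biomass_reaction if base.biomass_reaction not in deleted else None
        ),
    )
    truth = {
        "deleted": sorted(deleted),
        "flipped": sorted(flip),
        "common_keys": {reaction_key(r) for r in survivors},
        "mapping": {r.id: r.id for r in survivors},
    }
    return base, copy, truth


@dataclass
class Collection:
    """A synthetic model collection with planted subsystem structure."""

    models: list[MetabolicModel]
    subsystems: dict[str, list]  # label -> reaction keys (core namespace)
    truth: dict[str, Any]
    features: FeatureTable | None = None


def make_collection(
    n_models: int = 12,
    seed: int = 0,
    core_metabolites: int = 30,
    variable_branches: tuple[int, int] = (2, 5),
    standard_sites: int = 2,
) -> Collection:
    """Collection of models sharing a core pathway, with planted structure.

    All models share an identical core chain (plus exchanges).  The chain is
    split into three segments of reactions labelled as subsystems:

    - ``conserved``: no model-specific reactions attach anywhere near —
      identical network context in every model, hence high cross-model
      sensitivity correlations;
    - ``variable``: each model attaches its own branch reactions at
      randomly chosen metabolites of this segment (random count drawn from
      ``variable_branches``), so the local network context — and hence the
      flux response to perturbing these reactions — differs per model;
    - ``standard``: branches attach at the same fixed sites in every model
      but with per-model random stoichiometric coefficients, a mild and
      uniform level of divergence.

    The planted classification (which labels should come out conserved /
    variable) is returned as ground truth.
    """
    rng = np.random.default_rng(seed)
    m = core_metabolites
    seg = (m - 1) // 3  # chain reactions per segment
    met_names = [f"C{i}" for i in range(m)]

    def canon(name: str) -> str:
        return _metabolite(name).canonical_id

    # segment layout along the chain: conserved | standard | variable
    conserved_rxns = [f"R_core_{i}" for i in range(seg)]
    standard_rxns = [f"R_core_{i}" for i in range(seg, 2 * seg)]
    variable_rxns = [f"R_core_{i}" for i in range(2 * seg, m - 1)]
    variable_site_pool = np.arange(2 * seg, m - 1)
    fixed_standard_sites = [
        met_names[i]
        for i in rng.choice(
            np.arange(seg, 2 * seg), size=standard_sites, replace=False
        )
    ]

    models = []
    for li in range(n_models):
        metabolites = [_metabolite(name) for name in met_names]
        reactions = []
        for i in range(m - 1):
            label = (
                "conserved" if i < seg
                else "standard" if i < 2 * seg
                else "variable"
            )
            reactions.append(
                Reaction(
                    id=f"R_core_{i}",
                    stoichiometry={canon(met_names[i]): -1.0,
                                   canon(met_names[i + 1]): 1.0},
                    subsystem=label,
                )
            )
        for name in (met_names[0], met_names[-1]):
            reactions.append(
                Reaction(
                    id=f"EX_{name}",
                    stoichiometry={canon(name): -1.0},
                    reversible=True,
                    subsystem="exchange",
                )
            )
        # model-specific branches
        branch_no = 0

        def attach(site: str, mets: list[Metabolite], rxns: list[Reaction]):
            nonlocal branch_no
            aux = _metabolite(f"X_{li}_{branch_no}")
            mets.append(aux)
            coef_in = float(rng.choice([1, 2]))
            coef_out = float(rng.choice([1, 2]))
            rxns.append(
                Reaction(
                    id=f"R_acc_{li}_{branch_no}",
                    stoichiometry={canon(site): -coef_in,
                                   aux.canonical_id: coef_out},
                    subsystem="accessory",
                )
            )
            rxns.append(
                Reaction(
                    id=f"EX_acc_{li}_{branch_no}",
                    stoichiometry={aux.canonical_id: -1.0},
                    reversible=True,
                    subsystem="accessory",
                )
            )
            branch_no += 1

        n_var = int(rng.integers(variable_branches[0], variable_branches[1] + 1))
        var_sites = rng.choice(variable_site_pool, size=n_var, replace=False)
        for i in var_sites:
            attach(met_names[i], metabolites, reactions)
        for site in fixed_standard_sites:
            attach(site, metabolites, reactions)
        models.append(
            MetabolicModel(
                id=f"org{li:02d}", metabolites=metabolites, reactions=reactions
            )
        )

    key_of = {r.id: reaction_key(r) for r in models[0].reactions
              if r.id.startswith(("R_core_", "EX_C"))}
    subsystems = {
        "conserved": [key_of[r] for r in conserved_rxns],
        "standard": [key_of[r] for r in standard_rxns],
        "variable": [key_of[r] for r in variable_rxns],
    }
    truth = {
        "planted": {"conserved": "conserved", "variable": "variable"},
        "core_reactions": sorted(key_of),
    }
    return Collection(models=models, subsystems=subsystems, truth=truth)


def make_feature_study(
    n_models: int = 40,
    seed: int = 0,
    effects: dict[str, float] | None = None,
    intercept: float = 0.0,
    noise_sd: float = 0.25,
    n_profiles: int = 8,
    feature_classes: dict[str, str] | None = None,
) -> tuple[FeatureTable, dict[tuple[str, str], float], dict[str, float]]:
    """Feature table plus pair responses with planted linear effects.

    Models are assigned one of ``n_profiles`` distinct binary feature
    vectors (each profile repeated, so pairs with identical features exist);
    the response of a pair (l, m) sharing profile F is
    ``intercept + sum_p b_p F_p + noise``.  Returns the table, the
    responses over all identical-feature pairs, and the planted
    coefficients.
    """
    rng = np.random.default_rng(seed)
    effects = dict(effects or {"habitat_aquatic": 0.5, "thermophile": -0.3})
    names = list(effects)
    n_feat = len(names)
    profiles = {tuple(rng.integers(0, 2, size=n_feat)) for _ in range(200)}
    profiles = sorted(profiles)[:n_profiles]
    if len(profiles) < 2:
        raise ValueError("need at least two distinct feature profiles")
    rows = [profiles[i % len(profiles)] for i in range(n_models)]
    model_ids = [f"org{i:02d}" for i in range(n_models)]
    table = FeatureTable(
        model_ids=model_ids,
        feature_names=names,
        values=np.array(rows),
        classes=feature_classes or {n: n.split("_")[0] for n in names},
    )
    b = np.array([effects[n] for n in names], dtype=float)
    responses = {}
    for (i, a), (j, c) in combinations(enumerate(model_ids), 2):
        if rows[i] == rows[j]:
            mean = intercept + float(np.array(rows[i]) @ b)
            responses[(a, c)] = mean + float(rng.normal(0.0, noise_sd))
    truth = {"intercept": intercept, **effects}
    return table, responses, truth
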