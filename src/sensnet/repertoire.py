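"""Reaction-set (Jaccard) similarity and reaction-graph distances.

The metabolic repertoire view ignores fluxes entirely: two models are
compared by which reactions they contain (``J_M``), what the graph
neighborhood of a shared reaction looks like (``J_R``), and how much of a
subsystem's reaction set they share (``J_S``).  The graph underlying the
neighborhoods is the unweighted reaction-adjacency graph: reactions are
nodes, connected when they share at least one metabolite; distances are
shortest path lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import networkx as nx
import numpy as np

from .model import MetabolicModel, ReactionKey

__all__ = [
    "ReactionGraph",
    "graph_distances",
    "neighborhood",
    "jaccard_models",
    "jaccard_reaction",
    "jaccard_subsystem",
    "normalized_jaccard_subsystem",
]


@dataclass
class ReactionGraph:
    """Reaction-adjacency graph of one model with shortest-path distances."""

    model_id: str
    graph: nx.Graph
    _dist_cache: dict[ReactionKey, dict[ReactionKey, int]] = field(
        default_factory=dict, repr=False
    )

    def distance(self, k: ReactionKey, i: ReactionKey) -> float:
        """Graph distance D_G(k, i); ``inf`` if unreachable."""
        return self._lengths(k).get(i, inf)

    def neighborhood(self, k: ReactionKey, radius: int = 1) -> set[ReactionKey]:
        """N(l, k): reactions within graph distance ``radius`` of k
        (k itself included, D_G(k, k) = 0)."""
        if k not in self.graph:
            raise KeyError(f"reaction {k} not in model {self.model_id!r}")
        lengths = self._lengths(k)
        return {i for i, d in lengths.items() if d <= radius}

    def _lengths(self, k: ReactionKey) -> dict[ReactionKey, int]:
        if k not in self.graph:
            raise KeyError(f"reaction {k} not in model {self.model_id!r}")
        if k not in self._dist_cache:
            self._dist_cache[k] = dict(
                nx.single_source_shortest_path_length(self.graph, k)
            )
        return self._dist_cache[k]


def graph_distances(
    model: MetabolicModel, exclude_metabolites: set[str] | None = None
) -> ReactionGraph:
    """Build the reaction-adjacency graph of ``model``.

    Two reactions are adjacent when they share any metabolite.  All shared
    metabolites count by default; ``exclude_metabolites`` (canonical ids)
    can drop currency metabolites from the adjacency if desired.
    """
    exclude = exclude_metabolites or set()
    key_of = {i: k for k, i in model.key_to_index().items()}
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(key_of.values())
    met_members: dict[str, list[ReactionKey]] = {}
    for i, key in key_of.items():
        for met in model.reactions[i].stoichiometry:
            if met not in exclude:
                met_members.setdefault(met, []).append(key)
    for members in met_members.values():
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                g.add_edge(members[a_idx], members[b_idx])
    return ReactionGraph(model_id=model.id, graph=g)


def neighborhood(
    graph: ReactionGraph, k: ReactionKey, radius: int = 1
) -> set[ReactionKey]:
    return graph.neighborhood(k, radius)


def _jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        raise ValueError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def jaccard_models(l: MetabolicModel, m: MetabolicModel) -> float:
    """J_M(l, m) = |R_l & R_m| / |R_l | R_m| on reaction formulas."""
    return _jaccard(set(l.key_to_index()), set(m.key_to_index()))


def jaccard_reaction(
    l: MetabolicModel,
    m: MetabolicModel,
    k: ReactionKey,
    radius: int = 1,
    graphs: tuple[ReactionGraph, ReactionGraph] | None = None,
) -> float:
    """J_R(l, m, k): Jaccard of k's graph neighborhoods in the two models.

    Each neighborhood is computed within its own model's full reaction
    graph (not the common subgraph).  Pass precomputed ``graphs`` to avoid
    rebuilding them per reaction.
    """
    if graphs is None:
        graphs = (graph_distances(l), graph_distances(m))
    g_l, g_m = graphs
    return _jaccard(g_l.neighborhood(k, radius), g_m.neighborhood(k, radius))


def jaccard_subsystem(
    l: MetabolicModel, m: MetabolicModel, subsystem: set[ReactionKey]
) -> float | None:
    """J_S(l, m, S_j) = |S_j & R_l & R_m| / |S_j & (R_l | R_m)|.

    Returns None (undefined) when the subsystem is disjoint from both
    models' repertoires.
    """
    if not subsystem:
        raise ValueError("empty subsystem")
    keys_l = set(l.key_to_index())
    keys_m = set(m.key_to_index())
    denom = subsystem & (keys_l | keys_m)
    if not denom:
        return None
    return len(subsystem & keys_l & keys_m) / len(denom)


def normalized_jaccard_subsystem(
    j_s: float, j_m_values: np.ndarray | list[float]
) -> float:
    """~J_S: center a subsystem Jaccard by the model-level Jaccard
    distribution over all pairs and scale by its standard deviation."""
    j_m_values = np.asarray(j_m_values, dtype=float)
    sd = j_m_values.std(ddof=1) if j_m_values.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("zero variance in model-level Jaccard indices")
    return float((j_s - j_m_values.mean()) / sd)
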