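"""Absolute structural sensitivities of steady-state flux networks.

Perturbing the flux of reaction ``k`` by an amount ``delta`` forces the rest
of the network to readjust.  Assuming cells redistribute fluxes minimally,
the adjustment ``d`` is the minimum-2-norm vector satisfying

    N @ d = 0          (steady state)
    d[k]  = delta      (the imposed perturbation)

and the sensitivity vector is ``s = d / delta``.  With ``P`` the orthogonal
projector onto null(N) (obtained from the SVD of N), the solution is the
closed form ``d = delta * P[:, k] / P[k, k]``; a reaction with
``P[k, k] ~ 0`` cannot carry steady-state flux at all and the perturbation
is undefined (the reaction is *blocked*).  No operating state, flux bounds
or environment enter: the sensitivities are a property of the stoichiometry
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svd

from .model import MetabolicModel, ReactionKey

__all__ = [
    "NullSpaceProjector",
    "SensitivityMatrix",
    "nullspace_projector",
    "perturb_reaction",
    "perturb_gene",
    "sensitivity_matrix",
    "BlockedReactionError",
    "GenePerturbationInfeasibleError",
]


class BlockedReactionError(ValueError):
    """Perturbation of a reaction that cannot carry steady-state flux."""


class GenePerturbationInfeasibleError(ValueError):
    """No steady-state adjustment fixes all of a gene's reactions to delta."""


@dataclass
class NullSpaceProjector:
    """Orthogonal projector ``P = K @ K.T`` onto null(N).

    ``K``'s columns are an orthonormal null-space basis from the SVD of N;
    singular values below ``svd_tolerance * sigma_max`` count as zero.
    ``P[k, k]`` is the squared norm of reaction ``k``'s component in the
    null space — zero exactly for blocked reactions.
    """

    P: np.ndarray
    nullity: int
    svd_tolerance: float

    @property
    def diag(self) -> np.ndarray:
        return np.diag(self.P)

    def blocked_mask(self) -> np.ndarray:
        return self.diag <= self.svd_tolerance

    @property
    def n_reactions(self) -> int:
        return self.P.shape[0]


def nullspace_projector(
    model_or_N: MetabolicModel | np.ndarray, svd_tolerance: float | None = None
) -> NullSpaceProjector:
    """Projector onto the null space of a model's stoichiometric matrix.

    ``svd_tolerance`` is the relative singular-value cutoff; the default is
    the standard numerical-rank rule ``max(N.shape) * eps``.  A null space
    of dimension zero yields ``P = 0`` (every reaction blocked), which is a
    valid, fully degenerate result.
    """
    N = model_or_N.N if isinstance(model_or_N, MetabolicModel) else np.asarray(
        model_or_N, dtype=float
    )
    if N.size == 0:
        raise ValueError("empty stoichiometric matrix")
    if svd_tolerance is None:
        svd_tolerance = max(N.shape) * np.finfo(float).eps
    _, sv, Vt = svd(N, full_matrices=True)
    cutoff = svd_tolerance * (sv[0] if sv.size else 1.0)
    rank = int(np.sum(sv > cutoff))
    K = Vt[rank:].T  # orthonormal basis of null(N)
    P = K @ K.T
    return NullSpaceProjector(P=P, nullity=K.shape[1], svd_tolerance=svd_tolerance)


def perturb_reaction(
    proj: NullSpaceProjector, k: int, delta: float = 1.0
) -> np.ndarray:
    """Sensitivity vector ``s = d / delta`` for a unit perturbation of ``k``.

    ``d = delta * P[:, k] / P[k, k]`` is the unique least-norm steady-state
    adjustment with ``d[k] = delta``; the returned ``s`` has ``s[k] = 1``
    exactly and is independent of ``delta``.
    """
    pkk = proj.P[k, k]
    if pkk <= proj.svd_tolerance:
        raise BlockedReactionError(
            f"reaction index {k} is blocked (projector diagonal {pkk:.3g})"
        )
    s = proj.P[:, k] / pkk
    s[k] = 1.0
    return s


def perturb_gene(
    proj: NullSpaceProjector, reactions: list[int] | set[int], delta: float = 1.0
) -> np.ndarray:
    """Sensitivity of a simultaneous perturbation of a gene's reactions.

    All reactions in ``reactions`` are fixed to the same perturbation
    ``delta`` and the least-norm steady-state adjustment over the remaining
    degrees of freedom is returned (divided by ``delta``).  Solves
    ``(E.T @ P @ E) c = delta * 1`` with ``d = P @ E @ c``, falling back to
    the pseudo-inverse when the Gram matrix is singular; infeasibility (some
    requested entry cannot reach ``delta`` in null(N)) raises.
    """
    G = sorted(set(reactions))
    if not G:
        raise ValueError("empty reaction set for gene perturbation")
    if len(G) == 1:
        return perturb_reaction(proj, G[0], delta)
    PE = proj.P[:, G]  # P @ E_G
    gram = PE[G, :]  # E_G^T P E_G
    rhs = np.ones(len(G))
    try:
        coef = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        coef = np.linalg.pinv(gram) @ rhs
    s = PE @ coef
    feas_tol = 1e-8 * max(1.0, float(np.abs(s).max()))
    if not np.allclose(s[G], 1.0, atol=feas_tol):
        raise GenePerturbationInfeasibleError(
            f"no steady-state adjustment fixes reactions {G} to a common delta"
        )
    s[G] = 1.0
    return s


@dataclass
class SensitivityMatrix:
    """All-vs-all sensitivities of one model.

    ``S[i, k]`` is the response of reaction ``i`` to a unit perturbation of
    reaction ``k`` (columns are perturbations), expressed in the model's
    written reaction directions.  Blocked reactions have NaN columns (their
    perturbation is undefined) and are listed in ``blocked``.
    """

    model_id: str
    reaction_index: list[ReactionKey]
    S: np.ndarray
    delta: float = 1.0
    blocked: set[ReactionKey] = field(default_factory=set)
    blocked_positions: frozenset[int] = frozenset()

    def column(self, k: int) -> np.ndarray:
        if k in self.blocked_positions:
            raise BlockedReactionError(f"reaction position {k} is blocked")
        return self.S[:, k]


def sensitivity_matrix(
    model: MetabolicModel, svd_tolerance: float | None = None
) -> SensitivityMatrix:
    """Perturb every unblocked reaction of ``model`` with delta = 1.

    The k-th column is ``perturb_reaction(proj, k)``; reactions whose
    projector diagonal vanishes are recorded as blocked and excluded from
    downstream correlation index sets.
    """
    proj = nullspace_projector(model, svd_tolerance)
    n = proj.n_reactions
    d = proj.diag
    mask = proj.blocked_mask()
    S = np.full((n, n), np.nan)
    unblocked = np.flatnonzero(~mask)
    if unblocked.size:
        cols = proj.P[:, unblocked] / d[unblocked]
        cols[unblocked, np.arange(unblocked.size)] = 1.0
        S[:, unblocked] = cols
    keys = model.reaction_keys
    return SensitivityMatrix(
        model_id=model.id,
        reaction_index=list(keys),
        S=S,
        delta=1.0,
        blocked={keys[i] for i in np.flatnonzero(mask)},
        blocked_positions=frozenset(int(i) for i in np.flatnonzero(mask)),
    )
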