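"""Sensitivity correlations between models.

The functional similarity of a reaction ``k`` common to two models ``l`` and
``m`` is the correlation of the two models' sensitivity responses to
perturbing ``k``, both restricted to the common reaction set and sorted in
the same order:

    S(l, m, k) = rho( s(R_l & R_m, k, l), s(R_l & R_m, k, m) )

``rho`` is either the Pearson product-moment correlation or a Gaussian-rank
("copula") correlation that is invariant to the marginal distributions.
Averaging over a reaction set gives S(l, m, R); over all common reactions it
gives the model-level similarity S_M and distance D = 1 - |S_M|.

Models may write the same biochemical reaction in opposite directions, which
flips the sign of its flux.  Before correlating, each responding reaction's
entry is flipped to its canonical orientation, and a whole response vector
is flipped when the *perturbed* reaction is written opposite to canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import ReactionKey
from .sensitivity import SensitivityMatrix

__all__ = [
    "SimilarityRecord",
    "ModelSimilarity",
    "pearson",
    "copula_correlation",
    "reaction_similarity",
    "set_similarity",
    "model_similarity",
    "common_unblocked",
]

MIN_COMMON = 3  # a correlation over fewer than 3 points is meaningless


@dataclass
class SimilarityRecord:
    model_pair: tuple[str, str]
    reaction: ReactionKey
    method: str
    value: float
    n_common: int
    valid: bool = True
    degenerate: bool = False  # zero-variance profile; value forced to 0


@dataclass
class ModelSimilarity:
    model_pair: tuple[str, str]
    S_M: float
    D: float
    per_reaction: list[SimilarityRecord] = field(default_factory=list)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; 0 for zero-variance input (see
    :func:`reaction_similarity`, which flags such records)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < MIN_COMMON:
        raise ValueError(f"need at least {MIN_COMMON} points")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (x.size + 1))


def copula_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-rank correlation: Pearson on normal scores of the ranks.

    Ties get mean ranks; rank r maps to the standard-normal quantile at
    r/(n+1).  Invariant under strictly increasing transforms of either
    argument, hence unaffected by the marginals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < MIN_COMMON:
        raise ValueError(f"need at least {MIN_COMMON} points")
    return pearson(_normal_scores(x), _normal_scores(y))


_METHODS = {"pearson": pearson, "copula": copula_correlation}


def common_unblocked(
    sm_l: SensitivityMatrix, sm_m: SensitivityMatrix
) -> list[ReactionKey]:
    """Common reactions unblocked in both models, in a deterministic order.

    Duplicated formulas within one model collapse to their first occurrence.
    """
    pos_l = _key_positions(sm_l)
    pos_m = _key_positions(sm_m)
    shared = [
        k
        for k in pos_l
        if k in pos_m and k not in sm_l.blocked and k not in sm_m.blocked
    ]
    return sorted(shared, key=lambda k: k.canonical_form)


def _key_positions(sm: SensitivityMatrix) -> dict[ReactionKey, int]:
    pos: dict[ReactionKey, int] = {}
    for i, k in enumerate(sm.reaction_index):
        pos.setdefault(k, i)
    return pos


def _canonical_profiles(
    sm: SensitivityMatrix, common: list[ReactionKey]
) -> np.ndarray:
    """Sign-reconciled sensitivity submatrix over the common set.

    Entry (i, k) is the canonical-orientation response of common reaction i
    to a canonical-orientation unit perturbation of common reaction k.
    """
    pos = _key_positions(sm)
    idx = np.array([pos[k] for k in common], dtype=int)
    signs = np.array(
        [sm.reaction_index[pos[k]].orientation_sign for k in common], dtype=float
    )
    sub = sm.S[np.ix_(idx, idx)]
    return sub * np.outer(signs, signs)


def reaction_similarity(
    sm_l: SensitivityMatrix,
    sm_m: SensitivityMatrix,
    k: ReactionKey,
    common: list[ReactionKey] | None = None,
    method: str = "pearson",
) -> SimilarityRecord:
    """S(l, m, k): correlation of the two models' responses to perturbing k."""
    if common is None:
        common = common_unblocked(sm_l, sm_m)
    if k not in set(common):
        raise KeyError(f"reaction {k} not in the common set")
    if k in sm_l.blocked or k in sm_m.blocked:
        raise ValueError(f"reaction {k} is blocked in one of the models")
    col = common.index(k)
    prof_l = _canonical_profiles(sm_l, common)[:, col]
    prof_m = _canonical_profiles(sm_m, common)[:, col]
    return _record(sm_l, sm_m, k, prof_l, prof_m, method)


def _record(sm_l, sm_m, k, prof_l, prof_m, method) -> SimilarityRecord:
    pair = (sm_l.model_id, sm_m.model_id)
    n = prof_l.size
    if n < MIN_COMMON:
        return SimilarityRecord(pair, k, method, np.nan, n, valid=False)
    rho = _METHODS[method](prof_l, prof_m)
    degenerate = (np.ptp(prof_l) == 0.0) or (np.ptp(prof_m) == 0.0)
    return SimilarityRecord(pair, k, method, rho, n, degenerate=degenerate)


def set_similarity(records: list[SimilarityRecord]) -> float:
    """S(l, m, R): arithmetic mean of per-reaction similarities over R."""
    if not records:
        raise ValueError("empty reaction set")
    if any(not r.valid for r in records):
        raise ValueError("set contains invalid similarity records")
    return float(np.mean([r.value for r in records]))


def model_similarity(
    sm_l: SensitivityMatrix, sm_m: SensitivityMatrix, method: str = "pearson"
) -> ModelSimilarity:
    """S_M(l, m) over all common unblocked reactions, and D = 1 - |S_M|."""
    common = common_unblocked(sm_l, sm_m)
    if len(common) < MIN_COMMON:
        raise ValueError(
            f"models {sm_l.model_id!r} and {sm_m.model_id!r} share only "
            f"{len(common)} usable reactions (need {MIN_COMMON})"
        )
    prof_l = _canonical_profiles(sm_l, common)
    prof_m = _canonical_profiles(sm_m, common)
    records = [
        _record(sm_l, sm_m, k, prof_l[:, j], prof_m[:, j], method)
        for j, k in enumerate(common)
    ]
    s_m = set_similarity(records)
    return ModelSimilarity(
        model_pair=(sm_l.model_id, sm_m.model_id),
        S_M=s_m,
        D=float(1.0 - abs(s_m)),
        per_reaction=records,
    )
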