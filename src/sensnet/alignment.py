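"""Functional alignment of two networks by optimal assignment.

Each reaction is characterized by its sensitivity response restricted to a
small feature set F of common reactions; the cost of pairing reaction a of
model l with reaction b of model m is the sensitivity distance
``1 - |rho(profile_l(a), profile_m(b))|``.  Reaction identities are blinded:
only the profiles over F enter.  A globally optimal one-to-one mapping
minimizing total cost is found by a Jonker-Volgenant-type solver for the
(rectangular) linear assignment problem.

Alignments are evaluated with Enzyme Commission (EC) numbers: the EC
similarity level of two reactions is the longest shared prefix (0-4) over
all their EC pairs, and the EC score of an alignment compares the level
distribution among aligned pairs with the all-pairs null distribution,
Kullback-Leibler style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import ReactionKey
from .sensitivity import SensitivityMatrix

__all__ = [
    "CostMatrix",
    "AlignmentResult",
    "build_cost_matrix",
    "solve_assignment",
    "self_alignment_experiment",
    "ec_similarity_level",
    "ec_score",
]

MIN_FEATURES = 3


@dataclass
class CostMatrix:
    rows: list[ReactionKey]  # candidate reactions of model l
    cols: list[ReactionKey]  # candidate reactions of model m
    feature_set: list[ReactionKey]
    cost: np.ndarray  # entries in [0, 1]


@dataclass
class AlignmentResult:
    mapping: list[tuple[ReactionKey, ReactionKey]]
    unmapped: list[ReactionKey]
    total_cost: float
    row_indices: np.ndarray = field(repr=False, default=None)
    col_indices: np.ndarray = field(repr=False, default=None)


def _feature_profiles(
    sm: SensitivityMatrix, feature_positions: np.ndarray, signs: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """Columns = per-reaction responses on the feature set, canonical signs.

    Returns the (|F|, n_unblocked) profile matrix and the unblocked
    positions the columns correspond to.
    """
    unblocked = [
        i for i in range(len(sm.reaction_index)) if i not in sm.blocked_positions
    ]
    prof = sm.S[np.ix_(feature_positions, unblocked)] * signs[:, None]
    return prof, unblocked


def _abs_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson| between every column of a and every column of b.

    Zero-variance columns correlate 0 with everything (maximal distance)."""
    def norm_cols(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=0, keepdims=True)
        nrm = np.linalg.norm(xc, axis=0, keepdims=True)
        nrm[nrm == 0] = np.inf
        return xc / nrm

    return np.clip(np.abs(norm_cols(a).T @ norm_cols(b)), 0.0, 1.0)


def build_cost_matrix(
    sm_l: SensitivityMatrix,
    sm_m: SensitivityMatrix,
    feature_set: list[ReactionKey],
) -> CostMatrix:
    """Sensitivity-distance cost between all unblocked reaction pairs.

    ``feature_set`` must be common, unblocked reactions whose identities are
    known in both models (the anchors); responding entries are flipped to
    canonical orientation per model.  The perturbed reactions themselves are
    blinded — only their profiles over F enter the cost.
    """
    if len(feature_set) < MIN_FEATURES:
        raise ValueError(f"need at least {MIN_FEATURES} feature reactions")

    def positions_and_signs(sm: SensitivityMatrix):
        pos: dict[ReactionKey, int] = {}
        for i, k in enumerate(sm.reaction_index):
            pos.setdefault(k, i)
        try:
            idx = np.array([pos[k] for k in feature_set], dtype=int)
        except KeyError as exc:
            raise KeyError(f"feature reaction missing from {sm.model_id!r}: "
                           f"{exc}") from exc
        signs = np.array(
            [sm.reaction_index[i].orientation_sign for i in idx], dtype=float
        )
        return idx, signs

    idx_l, signs_l = positions_and_signs(sm_l)
    idx_m, signs_m = positions_and_signs(sm_m)
    prof_l, rows_pos = _feature_profiles(sm_l, idx_l, signs_l)
    prof_m, cols_pos = _feature_profiles(sm_m, idx_m, signs_m)
    cost = 1.0 - _abs_correlation(prof_l, prof_m)
    return CostMatrix(
        rows=[sm_l.reaction_index[i] for i in rows_pos],
        cols=[sm_m.reaction_index[i] for i in cols_pos],
        feature_set=list(feature_set),
        cost=cost,
    )


def solve_assignment(cost: CostMatrix) -> AlignmentResult:
    """Globally optimal one-to-one assignment of rows to columns.

    Rectangular matrices are allowed; min(rows, cols) pairs are mapped and
    the surplus reactions of the larger side are reported unmapped.
    """
    if cost.cost.size == 0:
        raise ValueError("empty cost matrix")
    if not np.all(np.isfinite(cost.cost)):
        raise ValueError("cost matrix has non-finite entries")
    rid, cid = linear_sum_assignment(cost.cost)
    order = np.argsort(rid)
    rid, cid = rid[order], cid[order]
    mapping = [(cost.rows[i], cost.cols[j]) for i, j in zip(rid, cid)]
    if len(cost.rows) >= len(cost.cols):
        unmapped = [cost.rows[i] for i in range(len(cost.rows)) if i not in set(rid)]
    else:
        unmapped = [cost.cols[j] for j in range(len(cost.cols)) if j not in set(cid)]
    return AlignmentResult(
        mapping=mapping,
        unmapped=unmapped,
        total_cost=float(cost.cost[rid, cid].sum()),
        row_indices=rid,
        col_indices=cid,
    )


def _tie_groups(sm: SensitivityMatrix, decimals: int = 10) -> dict[int, int]:
    """Group unblocked reactions whose full sensitivity profiles are equal.

    Returns position -> group id; reactions in one group are mutually
    indistinguishable by any profile-based alignment.
    """
    unblocked = [
        i for i in range(len(sm.reaction_index)) if i not in sm.blocked_positions
    ]
    cols = np.round(sm.S[np.ix_(unblocked, unblocked)], decimals)
    groups: dict[bytes, int] = {}
    out = {}
    for j, pos in enumerate(unblocked):
        sig = cols[:, j].tobytes()
        out[pos] = groups.setdefault(sig, len(groups))
    return out


def self_alignment_experiment(
    sm: SensitivityMatrix,
    feature_fraction: float,
    n_repeats: int = 10,
    seed: int | None = None,
) -> dict[str, float]:
    """Align a model with a reaction-shuffled copy of itself.

    Per repeat: a random fraction of the unblocked reactions serves as
    feature set, the copy's reaction order is randomized, the assignment is
    solved, and the fraction of reactions mapped back to themselves is
    scored.  Reactions whose full sensitivity profiles are exactly tied are
    indistinguishable in principle; a mapping within such a tie group counts
    as correct in ``fraction_correct`` and the strict same-reaction score is
    also reported as ``fraction_identical``.
    """
    rng = np.random.default_rng(seed)
    unblocked = [
        i for i in range(len(sm.reaction_index)) if i not in sm.blocked_positions
    ]
    n = len(unblocked)
    n_features = max(MIN_FEATURES, round(feature_fraction * n))
    if n_features > n:
        raise ValueError("feature_fraction too small for a usable feature set")
    groups = _tie_groups(sm)

    correct, identical = [], []
    for _ in range(n_repeats):
        feat_pos = rng.choice(unblocked, size=n_features, replace=False)
        prof = sm.S[np.ix_(feat_pos, unblocked)]
        perm = rng.permutation(n)  # shuffled copy's reaction order
        prof_copy = prof[:, perm]
        cost = 1.0 - _abs_correlation(prof, prof_copy)
        rid, cid = linear_sum_assignment(cost)
        mapped_to = perm[cid]  # original position each row was mapped to
        rows = np.array(unblocked)[rid]
        targets = np.array(unblocked)[mapped_to]
        same = rows == targets
        same_group = np.array(
            [groups[r] == groups[t] for r, t in zip(rows, targets)]
        )
        identical.append(same.mean())
        correct.append(same_group.mean())
    return {
        "fraction_correct_mean": float(np.mean(correct)),
        "fraction_correct_sd": float(np.std(correct, ddof=1)) if n_repeats > 1 else 0.0,
        "fraction_identical_mean": float(np.mean(identical)),
        "n_features": n_features,
        "n_reactions": n,
        "n_repeats": n_repeats,
    }


def _ec_fields(ec: str) -> list[str]:
    fields = [f for f in ec.strip().split(".") if f not in ("", "-")]
    return fields[:4]


def ec_similarity_level(ecs_a: list[str], ecs_b: list[str]) -> int | None:
    """EC similarity: longest shared prefix (0-4), maximal over EC pairs.

    Partial EC numbers ('1.2.3.-') compare only up to their specified
    fields.  Returns None when either reaction has no EC annotation.
    """
    if not ecs_a or not ecs_b:
        return None
    best = 0
    for a in ecs_a:
        fa = _ec_fields(a)
        for b in ecs_b:
            fb = _ec_fields(b)
            level = 0
            for x, y in zip(fa, fb):
                if x == y:
                    level += 1
                else:
                    break
            best = max(best, level)
    return best


def ec_score(aligned_levels: list[int], null_levels: list[int]) -> float:
    """E(l, m) = sum_i a_i * log(a_i / n_i) over EC levels i = 0..4.

    ``a`` is the level distribution among aligned pairs, ``n`` among all
    cross-model reaction pairs (the null); natural log, 0*log(0/n) = 0.
    """
    if not aligned_levels or not null_levels:
        raise ValueError("empty level lists")
    a = np.bincount(aligned_levels, minlength=5)[:5] / len(aligned_levels)
    n = np.bincount(null_levels, minlength=5)[:5] / len(null_levels)
    score = 0.0
    for i in range(5):
        if a[i] > 0:
            if n[i] == 0:
                raise ValueError(
                    f"aligned pairs at EC level {i} absent from the null"
                )
            score += a[i] * np.log(a[i] / n[i])
    return float(score)
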