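"""Multi-model normalization and subsystem conservation analysis.

Across a collection of models, a reaction's average cross-pair sensitivity
correlation S_R(k) could in principle depend on how widely the reaction is
used (its usage rho(k) = fraction of models containing it).  To remove any
such trend, per-record similarities are normalized against a linear
regression of S_R on rho:

    ~S(l, m, k) = ( S(l, m, k) - b0 - b1 * rho(k) ) / sigma

with sigma the regression's root mean squared error.  When the slope is
negligible this is an ordinary z-score; its per-reaction average ~S_R(k) is
the reaction's "normalized bias".  Subsystems whose biases are
significantly positive (negative) relative to all reactions are classified
as conserved (variable); the rest are standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .model import MetabolicModel, ReactionKey
from .similarity import SimilarityRecord

__all__ = [
    "UsageTable",
    "UsageRegression",
    "NormalizedBias",
    "SubsystemCall",
    "usage_table",
    "average_reaction_similarity",
    "fit_usage_regression",
    "normalize",
    "classify_subsystems",
    "enrichment",
]


@dataclass
class UsageTable:
    """Which models contain each reaction, and the derived usage rho(k)."""

    model_ids: list[str]
    membership: dict[ReactionKey, set[str]]

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    def rho(self, k: ReactionKey) -> float:
        return len(self.membership[k]) / self.n_models

    def pairs(self, k: ReactionKey) -> list[tuple[str, str]]:
        """Unordered model pairs sharing reaction k (P_k, one per pair)."""
        return list(combinations(sorted(self.membership[k]), 2))

    def n_ordered_pairs(self, k: ReactionKey) -> int:
        n = len(self.membership[k])
        return n * (n - 1)


def usage_table(models: list[MetabolicModel]) -> UsageTable:
    if len(models) < 2:
        raise ValueError("usage requires at least two models")
    membership: dict[ReactionKey, set[str]] = {}
    for model in models:
        for k in model.key_to_index():
            membership.setdefault(k, set()).add(model.id)
    return UsageTable(model_ids=[m.id for m in models], membership=membership)


def average_reaction_similarity(
    records: list[SimilarityRecord], k: ReactionKey
) -> float:
    """S_R(k): mean similarity over all model pairs sharing k."""
    vals = [r.value for r in records if r.reaction == k and r.valid]
    if not vals:
        raise ValueError(f"no valid records for reaction {k}")
    return float(np.mean(vals))


@dataclass
class UsageRegression:
    b0_hat: float
    b1_hat: float
    sigma: float
    flagged: bool = False  # degenerate fit (constant usage or < 3 points)


def fit_usage_regression(
    s_r: np.ndarray | list[float], rho: np.ndarray | list[float]
) -> UsageRegression:
    """OLS of average reaction similarity S_R(k) on usage rho(k), all k.

    sigma is the RMSE of the residuals.  If every usage is identical the
    slope is undefined; the fit degrades to intercept = mean with slope 0
    and is flagged.
    """
    s_r = np.asarray(s_r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if s_r.shape != rho.shape:
        raise ValueError("length mismatch")
    flagged = s_r.size < 3
    if np.ptp(rho) == 0.0:
        b0, b1 = float(s_r.mean()), 0.0
        resid = s_r - b0
        flagged = True
    else:
        b1, b0 = np.polyfit(rho, s_r, 1)
        resid = s_r - (b0 + b1 * rho)
    sigma = float(np.sqrt(np.mean(resid**2)))
    return UsageRegression(b0_hat=float(b0), b1_hat=float(b1), sigma=sigma,
                           flagged=flagged)


@dataclass
class NormalizedBias:
    """Normalized (usage-regressed, z-scored) similarities at all levels."""

    regression: UsageRegression
    record_bias: list[tuple[tuple[str, str], ReactionKey, float]]
    reaction_bias: dict[ReactionKey, float]  # ~S_R(k)
    pair_bias: dict[tuple[str, str], float]  # ~S_M(l, m)

    def subsystem_bias(
        self, subsystems: dict[str, list[ReactionKey]]
    ) -> dict[str, float]:
        """~S_S(j): mean normalized bias of a subsystem's reactions."""
        out = {}
        for label, keys in subsystems.items():
            vals = [self.reaction_bias[k] for k in keys if k in self.reaction_bias]
            if vals:
                out[label] = float(np.mean(vals))
        return out


def normalize(
    records: list[SimilarityRecord],
    usage: UsageTable,
    regression: UsageRegression,
) -> NormalizedBias:
    """Apply the usage regression to every record and aggregate.

    Aggregates are the mean of normalized records per reaction (~S_R), per
    model pair (~S_M); subsystem means come from
    :meth:`NormalizedBias.subsystem_bias`.
    """
    if regression.sigma <= 0.0:
        raise ValueError("regression sigma must be positive to normalize")
    record_bias = []
    by_reaction: dict[ReactionKey, list[float]] = {}
    by_pair: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if not r.valid:
            continue
        z = (r.value - regression.b0_hat
             - regression.b1_hat * usage.rho(r.reaction)) / regression.sigma
        pair = tuple(sorted(r.model_pair))
        record_bias.append((pair, r.reaction, float(z)))
        by_reaction.setdefault(r.reaction, []).append(z)
        by_pair.setdefault(pair, []).append(z)
    return NormalizedBias(
        regression=regression,
        record_bias=record_bias,
        reaction_bias={k: float(np.mean(v)) for k, v in by_reaction.items()},
        pair_bias={p: float(np.mean(v)) for p, v in by_pair.items()},
    )


@dataclass
class SubsystemCall:
    label: str
    n_reactions: int
    mean_bias: float
    p_value: float
    category: str  # conserved | variable | standard
    test: str
    flagged: bool = False  # too few reactions to reach significance


def _test_shift(
    sample: np.ndarray,
    background: np.ndarray,
    test: str,
    rng: np.random.Generator,
    n_resamples: int,
) -> float:
    if test == "ranksum":
        return float(stats.mannwhitneyu(sample, background,
                                        alternative="two-sided").pvalue)
    if test == "signed_rank":
        centered = sample - np.median(background)
        if np.all(centered == 0):
            return 1.0
        return float(stats.wilcoxon(centered, alternative="two-sided").pvalue)
    if test == "empirical":
        obs = sample.mean()
        draws = rng.choice(background, size=(n_resamples, sample.size),
                           replace=True).mean(axis=1)
        centered = draws - background.mean()
        p = (np.sum(np.abs(centered) >= abs(obs - background.mean())) + 1) / (
            n_resamples + 1
        )
        return float(min(1.0, p))
    raise ValueError(f"unknown test {test!r}")


def classify_subsystems(
    bias: NormalizedBias,
    subsystems: dict[str, list[ReactionKey]],
    scheme: str = "by_reaction",
    alpha: float = 0.05,
    n_s: int = 100,
    n_r: int = 100,
    test: str = "ranksum",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> list[SubsystemCall]:
    """Classify each subsystem as conserved, variable or standard.

    Three alternative sampling schemes build the subsystem distribution
    that is tested against the all-reactions background:

    - ``by_reaction``: the per-reaction biases ~S_R(k), k in S_j;
    - ``alignment_sample``: n_s record-level biases ~S(l, m, k) sampled
      from the subsystem's records;
    - ``bootstrap``: n_r means of n_s record-level samples each.

    The background uses the same construction over all reactions.  A
    subsystem is conserved (variable) when its mean bias is positive
    (negative) and the two-sided test rejects at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    all_reaction_bias = np.array(list(bias.reaction_bias.values()))
    all_record_bias = np.array([z for _, _, z in bias.record_bias])
    by_reaction_records: dict[ReactionKey, list[float]] = {}
    for _, k, z in bias.record_bias:
        by_reaction_records.setdefault(k, []).append(z)

    calls = []
    for label in sorted(subsystems):
        keys = [k for k in subsystems[label] if k in bias.reaction_bias]
        if not keys:
            continue
        mean_bias = float(np.mean([bias.reaction_bias[k] for k in keys]))
        if len(keys) < 2:
            calls.append(SubsystemCall(label, len(keys), mean_bias, 1.0,
                                       "standard", test, flagged=True))
            continue
        sub_records = np.array(
            [z for k in keys for z in by_reaction_records.get(k, [])]
        )
        if scheme == "by_reaction":
            sample = np.array([bias.reaction_bias[k] for k in keys])
            background = all_reaction_bias
        elif scheme == "alignment_sample":
            sample = rng.choice(sub_records, size=min(n_s, sub_records.size),
                                replace=True)
            background = rng.choice(all_record_bias, size=n_s, replace=True)
        elif scheme == "bootstrap":
            sample = rng.choice(
                sub_records, size=(n_r, min(n_s, sub_records.size)), replace=True
            ).mean(axis=1)
            background = rng.choice(
                all_record_bias, size=(n_r, n_s), replace=True
            ).mean(axis=1)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        p = _test_shift(sample, background, test, rng, n_resamples)
        if p < alpha and mean_bias > 0:
            category = "conserved"
        elif p < alpha and mean_bias < 0:
            category = "variable"
        else:
            category = "standard"
        calls.append(SubsystemCall(label, len(keys), mean_bias, p, category, test))
    return calls


def enrichment(
    calls: list[SubsystemCall],
    super_classes: dict[str, str],
    category: str,
    alpha: float = 0.05,
) -> dict[str, tuple[float, bool]]:
    """One-sided hypergeometric enrichment of a category per super class.

    ``super_classes`` maps subsystem label -> parent class.  For each parent
    class, tests whether it contains more ``category`` subsystems than
    expected when drawing its subsystems from the full collection.
    """
    labeled = [c for c in calls if c.label in super_classes]
    M = len(labeled)
    K = sum(1 for c in labeled if c.category == category)
    out = {}
    for parent in sorted(set(super_classes.values())):
        members = [c for c in labeled if super_classes[c.label] == parent]
        n = len(members)
        x = sum(1 for c in members if c.category == category)
        p = float(stats.hypergeom.sf(x - 1, M, K, n))
        out[parent] = (p, p < alpha)
    return out
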