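# Methods

## Model representation and cross-model reaction identity

A model is an ordered list of metabolites and reactions; the stoichiometric
matrix **N** (metabolites × reactions) is assembled from each reaction's
signed stoichiometry in the direction the source file writes it.
Compartments are part of metabolite identity (`glc__D[c]` ≠ `glc__D[e]`),
so transport reactions remain distinct from conversions.

Reactions are matched across models by a canonical key: the sorted tuple of
(metabolite, coefficient) pairs, oriented so that the direction whose
sorted substrate-id tuple is lexicographically smaller is canonical (with
the full signed form as tie-breaker). Two reactions share a key iff their
stoichiometries are identical up to overall sign; reversing a reaction
flips its recorded `orientation_sign` but not its key. This rule is
deterministic and uses only the metabolite namespace, so it is identical in
every model of a consistently-annotated collection. No cross-namespace
translation is attempted: comparing models annotated in different
namespaces yields an empty common set with a warning rather than spurious
matches. Duplicate identical formulas within one model collapse to the
first occurrence for cross-model matching (logged).

A consequence worth noting: single-metabolite boundary reactions ("A →"
and "→ A") are the same formula under sign-invariant identity, so a model
cannot contribute separate uptake and secretion pseudo-reactions for the
same metabolite to the common set.

## Curation

Automatically reconstructed models often contain reactions that can never
carry flux. Curation (1) checks that the biomass reaction attains a
strictly positive optimum with every exchange lower bound opened for
uptake; (2) runs flux variability analysis (FVA) under those bounds and
removes reactions whose minimum and maximum flux are both zero within the
LP tolerance; (3) re-maximizes biomass in the reduced model and, if the
optimum moved by more than max(lp_tolerance, 1e-6 relative), returns the
original model with the reduction flagged as rejected. All linear programs
use `scipy.optimize.linprog` (HiGHS) assembled directly from **N**; bounds
follow the declared reversibility with a default magnitude of 1000. The
relative floor of 1e-6 on the sanity check absorbs solver noise that a raw
1e-9 tolerance would misread as a change in optimum.

## Structural sensitivities

The null-space projector **P** = **KK**ᵀ is computed from the SVD of
**N**; singular values below `svd_tolerance · σ_max` count as zero, with
the standard numerical-rank default `max(N.shape) · eps`. The sensitivity
of the network to a unit perturbation of unblocked reaction *k* is
**s** = **P**e_k / P_kk, with s_k set to exactly 1; blocked reactions
(P_kk ≤ tolerance) are excluded from perturbation and from all correlation
index sets. Gene-level perturbations fix every reaction of the gene to the
same δ by solving the small Gram system (E_GᵀPE_G)c = δ·1, d = PE_G c, with
a pseudo-inverse fallback; if the resulting vector does not actually attain
δ on every constrained entry, the constraint set is empty and the
perturbation is reported infeasible.

Reversibility bounds are deliberately ignored here: the sensitivities are
pure null-space geometry and characterize responses independent of any
operating state. Bounds enter only through FVA curation, so "blocked by
FVA" and "blocked by projector" can differ; the latter governs the
sensitivity analysis and is recorded per model. Exchange pseudo-reactions
are perturbed exactly like internal reactions.

## Correlations and sign reconciliation

S(l,m,k) correlates the two models' response profiles restricted to the
common set, sorted identically. Two conventions matter:

- The perturbed reaction itself stays in the index set (its entries are 1
  in both profiles).
- Models may write a common reaction in opposite directions, which negates
  its flux entries. Before correlating, each responding entry is flipped to
  canonical orientation per model, and the whole profile is flipped when
  the perturbed reaction is written opposite to canonical. Direction-flip
  divergence is then exactly invisible (verified by test).

A profile with zero variance over the common set (a response confined to
the non-common part of the network) yields correlation 0 with a flag,
rather than NaN or a dropped reaction: such a response is evidence of
maximal dissimilarity, and silent NaN propagation is worse. Correlations
need at least 3 common reactions; smaller index sets give records flagged
invalid.

The copula correlation is the Gaussian-rank (normal-scores) estimator:
ranks with mean ties, quantile convention r/(n+1), then Pearson on the
transformed values. It is invariant to strictly monotone transforms of the
marginals. The estimator is configurable at the call sites because other
rank-based estimators exist and are defensible.

## Repertoire measures

The reaction-adjacency graph connects reactions sharing at least one
metabolite; edges are unweighted and distances are breadth-first shortest
paths. All shared metabolites count by default — no currency-metabolite
filter — because any exclusion list is a curation judgement; the option
exists (`exclude_metabolites`) and its effect on neighborhoods can be
large, which is a documented caveat of 1-neighborhood Jaccard indices.
Neighborhoods N(l,k) use each model's own full graph, include k itself
(distance 0), and grow monotonically with the radius.

## Usage normalization and subsystem classification

Across a collection, every valid per-record correlation S(l,m,k) is
normalized by the linear regression of per-reaction averages S_R(k) on
usage ρ(k) = |M_k|/|M|: ~S = (S − b̂₀ − b̂₁ρ)/σ with σ the regression RMSE.
When the slope is negligible this is z-scoring, and the per-reaction biases
have mean 0, sd 1 by construction. Unordered model pairs are used
throughout (S is symmetric; ordered pairs would duplicate every row and
silently halve downstream p-values).

Subsystems are classified by comparing a subsystem distribution against
the all-reactions background under three schemes: (i) per-reaction biases
~S_R(k); (ii) n_s = 100 record-level samples; (iii) n_r = 100 bootstrap
means of n_s = 100 record-level samples. The default test is the
two-sample Mann–Whitney rank-sum test (two-sided, α = 0.05); a one-sample
signed-rank test against the background median and an empirical p-value
from 10,000 size-matched resamples are available. The classification is
conserved / variable by the sign of the mean bias when significant,
standard otherwise; subsystems with fewer than two reactions are standard
with a flag. Reactions without a subsystem label pool into an "unassigned"
subset. Super-class enrichment uses the one-sided hypergeometric upper
tail. No multiple-testing correction is applied by default, matching the
single-test semantics of the classification; this inflates the family-wise
error over many subsystems and is the user's to handle when needed.

## Alignment and EC scoring

The cost of pairing reaction a of model l with reaction b of model m is
1 − |ρ| of their response profiles restricted to a feature set F of common
reactions (anchors); perturbed identities are blinded. The globally optimal
one-to-one mapping is found with `scipy.optimize.linear_sum_assignment`
(a Jonker-Volgenant-family solver; any optimal rectangular LAP solver
satisfies the contract, verified against brute force). Feature reactions
remain alignment candidates. In self-alignment experiments, reactions with
exactly tied full sensitivity profiles are indistinguishable in principle;
a mapping within a tie group counts as correct, and the strict
same-reaction fraction is reported alongside.

EC similarity of two reactions is the longest shared prefix (0–4) over all
their EC-number pairs; partial numbers compare only up to their specified
fields, and unannotated reactions are excluded. The alignment-level EC
score is Σᵢ aᵢ·ln(aᵢ/nᵢ) over levels i = 0..4, with a the aligned-pair
distribution, n the all-pairs null, natural log, and 0·ln(0/n) = 0.

## Trees and feature regressions

UPGMA merges the closest cluster pair at height d/2 and updates distances
by size-weighted averages; ties break on the lexicographically smallest
pair of cluster labels (a cluster is labelled by its smallest leaf), so the
tree is deterministic and invariant to input leaf order. Newick branch
lengths are parent–child height differences; serialize→parse round-trips
exactly, and the implementation is cross-checked against scipy's average
linkage via cophenetic distances.

THP regressions use model pairs with identical, fully specified feature
vectors (any −1 excludes the model); design rows are [1, F_l], responses
are normalized similarities (global or restricted to one subsystem's
reactions). Aliased feature columns — e.g. a feature nested inside a class
definition — are dropped greedily by rank test with a warning. A
coefficient is reported significant only when the F-test against the
constant model and its own two-sided t-test both reject at α. Per-feature
coefficients can be clustered by UPGMA on absolute differences.

## Synthetic data

The generators stand in for curated model collections and define the
conditions under which the framework is tested:

- `make_network`: a linear chain through all metabolites plus boundary
  exchanges guarantees connectivity and unblocked flux routes; remaining
  reactions are random sparse conversions with coefficients in {1, 2} and
  2–4 metabolites each — typical of curated reconstructions. Requires more
  reactions than metabolites so the null space is nontrivial.
- `make_pair`: divergence by deleting random non-exchange reactions (a
  randomly reduced copy) and/or flipping written directions; emits the true
  common set and mapping.
- `make_collection` (12 models by default): all models share a core chain
  partitioned into three labelled segments. The *conserved* segment has no
  model-specific attachments (identical context everywhere); the *variable*
  segment receives per-model branches at randomly chosen sites (2–5 per
  model), so local context differs between models; the *standard* segment
  has branches at the same fixed sites in every model with only coefficient
  variation. Site variation dominates coefficient variation in its effect
  on sensitivities, which is what makes the planted ordering
  conserved > standard > variable come out.
- `make_feature_study`: binary feature profiles repeated across models so
  identical-feature pairs exist, with pair responses drawn from the planted
  linear model plus Gaussian noise (sd 0.25 by default). Regression
  calibration (CI coverage, type-I error) is checked at this response level,
  where OLS theory gives exact expectations.

What the fixtures do not emulate: realistic pathway content,
thermodynamics, gene–reaction rules beyond simple lists, annotation noise,
or the heavy-tailed reaction-degree distributions of real GSMs. Passing
tests therefore demonstrate the correctness and calibration of the
machinery, not biological conclusions about real species.

## Problem sizes and numerical choices

The test suite and acceptance script run networks of 16–200 reactions,
collections of 12 models, 1000 random networks for the oracle comparison,
1000 null-subsystem simulations and 400 null regressions — sizes chosen so
the full analysis stays interactive on a laptop while estimates of rates
(α ≈ 0.05) have binomial standard errors below one percentage point.
Oracle agreement is required to 1e-8 (observed ~1e-13). SVD rank tolerance,
LP tolerance (1e-9) and the 1e-6 relative biomass sanity floor are exposed
as parameters.

## Known limitations

- Sensitivities are linear responses of the unconstrained null space;
  irreversibility, capacity bounds and operating points are ignored by
  design and may matter for strongly bounded networks.
- Cross-model identity requires a shared metabolite namespace; no
  MetaNetX-style translation is included.
- Correlation-based costs cannot separate reactions with exactly
  proportional sensitivity profiles (tie groups); alignments report them
  explicitly rather than resolving them arbitrarily.
- The usage regression is global; if usage–similarity relations differ by
  subsystem, the normalization removes only the global trend.
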