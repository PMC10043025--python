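import numpy as np
import pytest
from scipy import stats

from sensnet.model import ReactionKey
from sensnet.normalization import (
    NormalizedBias,
    UsageRegression,
    average_reaction_similarity,
    classify_subsystems,
    enrichment,
    fit_usage_regression,
    normalize,
    usage_table,
)
from sensnet.similarity import SimilarityRecord
from sensnet.synthetic import make_network


def fake_key(name: str) -> ReactionKey:
    return ReactionKey(canonical_form=((name, -1.0), (name + "_p", 1.0)))


def record(pair, k, value):
    return SimilarityRecord(pair, k, "pearson", value, 10)


class TestUsageTable:
    def test_counting(self):
        models = [make_network(seed=s, n_metabolites=6, n_reactions=9,
                               model_id=f"m{s}") for s in range(5)]
        ut = usage_table(models)
        # the chain backbone and boundary exchanges are shared by all
        shared = [k for k, mods in ut.membership.items() if len(mods) == 5]
        assert shared
        for k in shared:
            assert ut.rho(k) == 1.0
            assert len(ut.pairs(k)) == 10
            assert ut.n_ordered_pairs(k) == 20

    def test_partial_usage(self):
        ut_members = {fake_key("a"): {"m1", "m2", "m3"}}
        from sensnet.normalization import UsageTable

        ut = UsageTable(model_ids=["m1", "m2", "m3", "m4", "m5"],
                        membership=ut_members)
        k = fake_key("a")
        assert ut.rho(k) == pytest.approx(0.6)
        assert len(ut.pairs(k)) == 3

    def test_single_model_reaction_has_no_pairs(self):
        from sensnet.normalization import UsageTable

        ut = UsageTable(model_ids=["m1", "m2"],
                        membership={fake_key("a"): {"m1"}})
        assert ut.pairs(fake_key("a")) == []


class TestAverageReactionSimilarity:
    def test_mean_over_pairs(self):
        k = fake_key("a")
        recs = [record(("l", "m"), k, 0.5), record(("l", "n"), k, 0.7)]
        assert average_reaction_similarity(recs, k) == pytest.approx(0.6)

    def test_single_pair(self):
        k = fake_key("a")
        assert average_reaction_similarity(
            [record(("l", "m"), k, 0.42)], k
        ) == pytest.approx(0.42)

    def test_no_records_errors(self):
        with pytest.raises(ValueError):
            average_reaction_similarity([], fake_key("a"))


class TestUsageRegression:
    def test_perfect_constant_fit(self):
        reg = fit_usage_regression([0.5, 0.5, 0.5], [0.2, 0.5, 0.9])
        assert reg.b0_hat == pytest.approx(0.5)
        assert reg.b1_hat == pytest.approx(0.0, abs=1e-12)
        assert reg.sigma == pytest.approx(0.0, abs=1e-12)

    def test_planted_slope_recovery(self):
        rng = np.random.default_rng(1)
        rho = rng.uniform(0.1, 1.0, size=200)
        s_r = 0.2 + 0.3 * rho + rng.normal(0, 0.05, size=200)
        reg = fit_usage_regression(s_r, rho)
        # OLS standard errors for this design
        X = np.column_stack([np.ones(200), rho])
        cov = 0.05**2 * np.linalg.inv(X.T @ X)
        se_b0, se_b1 = np.sqrt(np.diag(cov))
        assert abs(reg.b0_hat - 0.2) < 3 * se_b0
        assert abs(reg.b1_hat - 0.3) < 3 * se_b1
        assert reg.sigma == pytest.approx(0.05, rel=0.2)

    def test_constant_usage_flagged(self):
        reg = fit_usage_regression([0.1, 0.5, 0.9], [1.0, 1.0, 1.0])
        assert reg.flagged
        assert reg.b1_hat == 0.0
        assert reg.b0_hat == pytest.approx(0.5)

    def test_two_points_interpolate(self):
        reg = fit_usage_regression([0.2, 0.4], [0.5, 1.0])
        assert reg.flagged
        assert reg.sigma == pytest.approx(0.0, abs=1e-12)
        assert reg.b0_hat + reg.b1_hat * 0.5 == pytest.approx(0.2)


class TestNormalize:
    def _usage(self, keys, model_ids=("l", "m")):
        from sensnet.normalization import UsageTable

        return UsageTable(
            model_ids=list(model_ids),
            membership={k: set(model_ids) for k in keys},
        )

    def test_z_score_arithmetic(self):
        k = fake_key("a")
        reg = UsageRegression(b0_hat=0.5, b1_hat=0.0, sigma=0.1)
        bias = normalize([record(("l", "m"), k, 0.7)], self._usage([k]), reg)
        assert bias.reaction_bias[k] == pytest.approx(2.0)

    def test_record_on_regression_line_is_zero(self):
        k = fake_key("a")
        reg = UsageRegression(b0_hat=0.3, b1_hat=0.2, sigma=0.05)
        bias = normalize([record(("l", "m"), k, 0.3 + 0.2 * 1.0)],
                         self._usage([k]), reg)
        assert bias.reaction_bias[k] == pytest.approx(0.0, abs=1e-12)

    def test_zero_sigma_rejected(self):
        k = fake_key("a")
        reg = UsageRegression(b0_hat=0.5, b1_hat=0.0, sigma=0.0)
        with pytest.raises(ValueError):
            normalize([record(("l", "m"), k, 0.7)], self._usage([k]), reg)

    def test_reaction_bias_is_z_scored(self):
        # per-reaction biases of a fitted collection have mean 0, sd 1
        rng = np.random.default_rng(2)
        s_r = rng.uniform(0.2, 0.9, size=150)
        rho = rng.uniform(0.2, 1.0, size=150)
        reg = fit_usage_regression(s_r, rho)
        z = (s_r - reg.b0_hat - reg.b1_hat * rho) / reg.sigma
        assert np.mean(z) == pytest.approx(0.0, abs=1e-10)
        assert np.std(z) == pytest.approx(1.0, abs=1e-10)

    def test_ordering_preserved_when_slope_zero(self):
        keys = [fake_key(f"k{i}") for i in range(5)]
        values = [0.1, 0.9, 0.4, 0.6, 0.2]
        reg = UsageRegression(b0_hat=0.5, b1_hat=0.0, sigma=0.2)
        recs = [record(("l", "m"), k, v) for k, v in zip(keys, values)]
        bias = normalize(recs, self._usage(keys), reg)
        order_raw = np.argsort(values)
        order_bias = np.argsort([bias.reaction_bias[k] for k in keys])
        assert np.array_equal(order_raw, order_bias)


def synthetic_bias(rng, n_reactions=500, shift_keys=(), shift=0.0,
                   records_per_reaction=4):
    """Record-level normalized biases: standard normal background with an
    optional planted mean shift on some reactions."""
    record_bias = []
    reaction_bias = {}
    for i in range(n_reactions):
        k = fake_key(f"k{i}")
        mu = shift if k in shift_keys else 0.0
        zs = rng.normal(mu, 1.0, size=records_per_reaction)
        for z in zs:
            record_bias.append((("l", "m"), k, float(z)))
        reaction_bias[k] = float(np.mean(zs))
    return NormalizedBias(
        regression=UsageRegression(0.0, 0.0, 1.0),
        record_bias=record_bias,
        reaction_bias=reaction_bias,
        pair_bias={},
    )


class TestClassifySubsystems:
    @pytest.mark.parametrize("scheme", ["by_reaction", "alignment_sample",
                                        "bootstrap"])
    def test_planted_shift_detected(self, scheme):
        rng = np.random.default_rng(7)
        shifted = {fake_key(f"k{i}") for i in range(30)}
        bias = synthetic_bias(rng, shift_keys=shifted, shift=2.0)
        calls = classify_subsystems(
            bias, {"planted": sorted(shifted, key=lambda k: k.canonical_form),
                   "rest": [fake_key(f"k{i}") for i in range(30, 90)]},
            scheme=scheme, seed=0,
        )
        by_label = {c.label: c for c in calls}
        assert by_label["planted"].category == "conserved"
        assert by_label["planted"].p_value < 0.05

    def test_negative_shift_is_variable(self):
        rng = np.random.default_rng(8)
        shifted = {fake_key(f"k{i}") for i in range(30)}
        bias = synthetic_bias(rng, shift_keys=shifted, shift=-2.0)
        calls = classify_subsystems(
            bias, {"planted": sorted(shifted, key=lambda k: k.canonical_form)},
            scheme="by_reaction",
        )
        assert calls[0].category == "variable"

    def test_null_subsystems_standard_at_alpha_rate(self):
        rng = np.random.default_rng(9)
        bias = synthetic_bias(rng, n_reactions=400)
        keys = sorted(bias.reaction_bias, key=lambda k: k.canonical_form)
        false_pos = 0
        n_sim = 300
        for i in range(n_sim):
            sub = rng.choice(len(keys), size=25, replace=False)
            calls = classify_subsystems(
                bias, {"null": [keys[j] for j in sub]}, scheme="by_reaction"
            )
            if calls[0].category != "standard":
                false_pos += 1
        rate = false_pos / n_sim
        assert rate < 0.10  # ~ alpha = 0.05 within binomial noise

    def test_small_subsystem_flagged_standard(self):
        rng = np.random.default_rng(10)
        bias = synthetic_bias(rng, n_reactions=50)
        k = sorted(bias.reaction_bias, key=lambda x: x.canonical_form)[0]
        calls = classify_subsystems(bias, {"tiny": [k]})
        assert calls[0].category == "standard"
        assert calls[0].flagged

    def test_empirical_p_agrees_with_ranksum(self):
        rng = np.random.default_rng(11)
        shifted = {fake_key(f"k{i}") for i in range(25)}
        bias = synthetic_bias(rng, shift_keys=shifted, shift=1.5)
        subsys = {"planted": sorted(shifted, key=lambda k: k.canonical_form)}
        for test in ("ranksum", "empirical"):
            calls = classify_subsystems(bias, subsys, test=test,
                                        n_resamples=2000, seed=3)
            assert calls[0].category == "conserved", test


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        # 5 of 5 drawn conserved from a pool of 10 with 5 conserved:
        # p = 1 / C(10, 5) = 1/252
        from sensnet.normalization import SubsystemCall

        calls = []
        for i in range(10):
            cat = "conserved" if i < 5 else "standard"
            parent = "classA" if i < 5 else "classB"
            calls.append(SubsystemCall(f"s{i}", 10, 1.0, 0.01, cat, "ranksum"))
        classes = {f"s{i}": ("classA" if i < 5 else "classB")
                   for i in range(10)}
        out = enrichment(calls, classes, "conserved")
        p, significant = out["classA"]
        assert p == pytest.approx(1 / 252)
        assert significant
        assert stats.hypergeom.sf(4, 10, 5, 5) == pytest.approx(1 / 252)
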