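"""Differential expression: normalization, dispersion, Wald test, FDR, ddCt."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from circena.config import PipelineConfig
from circena.diffexpr import (
    DEResult,
    bh_fdr,
    call_de,
    estimate_dispersion,
    nb_test,
    relative_expression_ddct,
    size_factors,
    term_enrichment,
)
from circena.synthetic import NBCountModel, simulate_counts


def nb_model(n, alpha, lfc=0.0, mean=100.0, sf=None, n_per_group=3):
    lfc = np.full(n, lfc) if np.isscalar(lfc) else lfc
    return NBCountModel(
        feature_ids=[f"g{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(2 * n_per_group)],
        base_mean=np.full(n, mean) if np.isscalar(mean) else mean,
        size_factors=np.ones(2 * n_per_group) if sf is None else sf,
        dispersion=np.full(n, alpha),
        group=np.repeat([0, 1], n_per_group),
        log2_fc=lfc,
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [5]]), (1, 4))
        assert size_factors(counts) == pytest.approx(np.ones(4))

    def test_doubled_column_doubles_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 100, size=(50, 1))
        counts = np.hstack([base, 2 * base, base])
        f = size_factors(counts)
        assert f[1] / f[0] == pytest.approx(2.0)
        assert f[2] / f[0] == pytest.approx(1.0)

    def test_single_feature_degenerates_to_normalized_counts(self):
        counts = np.array([[4, 16, 1]])
        f = size_factors(counts)
        assert f == pytest.approx(counts[0] / sps.gmean(counts[0]))

    def test_all_features_with_zeros_errors_and_fallback_works(self):
        counts = np.array([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(counts)
        f = size_factors(counts, pseudo_reference=True)
        assert np.all(f > 0)


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        cm, _ = simulate_counts(nb_model(1000, alpha=0.0), rng_seed=0)
        a = estimate_dispersion(cm.counts, np.ones(6), cm.groups_array())
        assert a.mean() <= 0.05

    def test_alpha_point_two_recovered_within_band(self):
        cm, _ = simulate_counts(nb_model(1000, alpha=0.2), rng_seed=1)
        a = estimate_dispersion(cm.counts, np.ones(6), cm.groups_array())
        assert 0.1 <= a.mean() <= 0.3

    def test_constant_counts_give_zero_alpha(self):
        counts = np.full((5, 6), 50)
        a = estimate_dispersion(counts, np.ones(6), np.repeat([0, 1], 3))
        assert a == pytest.approx(np.zeros(5))


class TestNbTest:
    def test_identical_groups_give_zero_lfc_and_p_one(self):
        counts = np.tile(np.array([[10, 20, 30]]), (1, 2))  # same triple twice
        res = nb_test(counts, np.ones(6), np.array([0.1]), np.repeat([0, 1], 3))
        assert res[0].log2_fc == pytest.approx(0.0)
        assert res[0].p_value == pytest.approx(1.0)

    def test_all_zero_feature_reported_not_dropped(self):
        counts = np.zeros((1, 6), dtype=int)
        res = nb_test(counts, np.ones(6), np.array([0.1]), np.repeat([0, 1], 3))
        assert res[0].p_value == 1.0 and res[0].log2_fc == 0.0

    def test_null_type_one_error_calibrated(self):
        """Under the null (lfc=0, alpha=0.1, 3+3, 2000 features) the fraction
        of p < 0.05 stays within 0.05 +/- 0.02."""
        cm, _ = simulate_counts(
            nb_model(2000, alpha=0.1, mean=np.random.default_rng(3).uniform(50, 500, 2000)),
            rng_seed=3,
        )
        sf = size_factors(cm.counts)
        groups = cm.groups_array()
        alpha = estimate_dispersion(cm.counts, sf, groups)
        res = nb_test(cm.counts, sf, alpha, groups)
        rate = np.mean([r.p_value < 0.05 for r in res])
        assert 0.03 <= rate <= 0.07

    def test_planted_two_fold_log_units_power(self, default_config):
        """|lfc| = 2 features at base mean 100 are recovered with power >= 0.8
        at FDR 0.05."""
        n, n_de = 1000, 100
        rng = np.random.default_rng(5)
        lfc = np.zeros(n)
        lfc[:n_de] = 2.0 * np.sign(rng.standard_normal(n_de))
        cm, _ = simulate_counts(nb_model(n, alpha=0.1, lfc=lfc), rng_seed=5)
        sf = size_factors(cm.counts)
        groups = cm.groups_array()
        res = nb_test(cm.counts, sf, estimate_dispersion(cm.counts, sf, groups),
                      groups)
        res = call_de(res, default_config)
        called = np.array([r.called for r in res])
        assert called[:n_de].mean() >= 0.8
        assert called[n_de:].mean() <= 0.01

    def test_invariant_to_within_group_relabeling_and_scaling(self):
        cm, _ = simulate_counts(nb_model(50, alpha=0.1), rng_seed=7)
        counts = cm.counts
        groups = cm.groups_array()
        sf = size_factors(counts)
        alpha = estimate_dispersion(counts, sf, groups)
        base = [r.p_value for r in nb_test(counts, sf, alpha, groups)]
        # swap two samples within the control group
        perm = [1, 0, 2, 3, 4, 5]
        p_perm = [
            r.p_value
            for r in nb_test(counts[:, perm], sf[perm], alpha, groups[perm])
        ]
        assert base == pytest.approx(p_perm)
        # doubling every count is absorbed by doubled size factors
        p_scaled = [
            r.p_value for r in nb_test(2 * counts, 2 * sf, alpha, groups)
        ]
        assert base == pytest.approx(p_scaled)


def brute_force_bh(p):
    """Independent step-up implementation used as the oracle."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_step_up(self, p):
        assert bh_fdr(p) == pytest.approx(brute_force_bh(np.array(p)))


class TestCallDe:
    def result(self, lfc, p):
        return DEResult("f", 10.0, lfc, p)

    def test_exact_two_fold_is_not_called(self, default_config):
        res = call_de([self.result(1.0, 1e-9)], default_config)
        assert not res[0].called  # fold change > 2 is strict

    def test_called_up(self, default_config):
        (r,) = call_de([self.result(1.5, 1e-4)], default_config)
        assert r.called and r.direction == "up"

    def test_high_fdr_blocks_call(self, default_config):
        (r,) = call_de([self.result(-3.0, 0.06)], default_config)
        assert not r.called and r.direction == "ns"

    def test_monotone_in_fdr_threshold(self, default_config):
        rng = np.random.default_rng(1)
        results = [
            DEResult(f"f{i}", 10.0, float(rng.normal(0, 2)), float(rng.uniform()))
            for i in range(200)
        ]
        loose = {
            r.feature_id
            for r in call_de(list(results), default_config.replace(fdr_threshold=0.1))
            if r.called
        }
        strict = {
            r.feature_id
            for r in call_de(list(results), default_config.replace(fdr_threshold=0.01))
            if r.called
        }
        assert strict <= loose


class TestRelativeExpressionDdct:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "group", "target_ct", "reference_ct"]
        )

    def test_one_cycle_above_control_mean_halves_expression(self):
        t = self.table(
            [("c1", "ctl", 20.0, 15.0), ("c2", "ctl", 20.0, 15.0),
             ("t1", "trt", 21.0, 15.0)]
        )
        out = relative_expression_ddct(t, "ctl")
        assert out.loc[out.sample_id == "t1", "fold_change"].item() == pytest.approx(0.5)

    def test_identical_samples_all_fold_one(self):
        t = self.table([(f"s{i}", "ctl" if i < 2 else "trt", 22.0, 16.0)
                        for i in range(4)])
        out = relative_expression_ddct(t, "ctl")
        assert out["fold_change"].to_numpy() == pytest.approx(np.ones(4))

    def test_minus_two_ddct_gives_fourfold(self):
        t = self.table(
            [("c1", "ctl", 20.0, 15.0), ("c2", "ctl", 20.0, 15.0),
             ("t1", "trt", 18.0, 15.0)]
        )
        out = relative_expression_ddct(t, "ctl")
        assert out.loc[out.sample_id == "t1", "fold_change"].item() == pytest.approx(4.0)

    def test_missing_reference_ct_errors(self):
        t = self.table([("c1", "ctl", 20.0, np.nan)])
        with pytest.raises(ValueError, match="missing"):
            relative_expression_ddct(t, "ctl")

    def test_technical_replicates_averaged(self):
        t = self.table(
            [("c1", "ctl", 20.0, 15.0), ("c1", "ctl", 22.0, 15.0),
             ("t1", "trt", 22.0, 15.0)]
        )
        t["replicate"] = [1, 2, 1]
        out = relative_expression_ddct(t, "ctl")
        assert len(out) == 2
        assert out.loc[out.sample_id == "t1", "fold_change"].item() == pytest.approx(0.5)


def hypergeom_two_sided(a, row1, col1, n):
    """Enumeration oracle: two-sided Fisher p by minimum-likelihood."""
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {
        k: sps.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)
    }
    target = probs[a]
    return sum(p for p in probs.values() if p <= target * (1 + 1e-9))


class TestTermEnrichment:
    def test_perfectly_enriched_term_closed_form(self):
        """A term equal to the 5 hits among 100 genes has
        p = 1 / C(100, 5)."""
        background = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(5)}
        out = term_enrichment(hits, background, {"T": set(hits)})
        from math import comb

        assert out.loc[0, "p_value"] == pytest.approx(1 / comb(100, 5))

    def test_empty_term_p_one(self):
        background = {f"g{i}" for i in range(20)}
        out = term_enrichment({"g1"}, background, {"T": set()})
        assert out.loc[0, "p_value"] == 1.0

    def test_null_term_p_uniform(self):
        """Terms independent of the hit list give approximately uniform
        p-values (KS check over random terms)."""
        rng = np.random.default_rng(11)
        background = {f"g{i}" for i in range(200)}
        hits = set(rng.choice(sorted(background), 40, replace=False))
        term_map = {
            f"T{t}": set(rng.choice(sorted(background), 30, replace=False))
            for t in range(2000)
        }
        out = term_enrichment(hits, background, term_map)
        # discrete p-values are conservative; KS against uniform is loose
        stat, _ = sps.kstest(out["p_value"], "uniform")
        assert stat < 0.25
        assert out["p_value"].min() > 1e-6

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals the exact hypergeometric tail sum on
        every 2x2 table with margins <= 30."""
        n = 30
        for row1, col1 in itertools.product([3, 7, 12, 19], repeat=2):
            background = {f"g{i}" for i in range(n)}
            hits = {f"g{i}" for i in range(row1)}
            lo, hi = max(0, row1 + col1 - n), min(row1, col1)
            for a in range(lo, hi + 1):
                term = {f"g{i}" for i in range(a)} | {
                    f"g{i}" for i in range(row1, row1 + col1 - a)
                }
                out = term_enrichment(hits, background, {"T": term})
                assert out.loc[0, "p_value"] == pytest.approx(
                    hypergeom_two_sided(a, row1, col1, n), rel=1e-8
                )

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            term_enrichment({"x"}, {"a", "b"}, {})
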