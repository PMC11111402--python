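"""Statistical-layer tests: exact-test oracles, regressions, timing filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geosig import (
    SBS96,
    AttributionResult,
    AttributionResults,
    PenaltyConfig,
    asr_regression,
    bh_adjust,
    clonal_subclonal_enrichment,
    country_burden_test,
    dichotomize,
    driver_spectrum_enrichment,
    filter_timing_samples,
    risk_factor_regression,
    wilcoxon_signed_rank,
)
from geosig.catalogue import CatalogueMatrix
from geosig.epi import fisher_exact_2x2


def _attr_result(sample, names, exposures, ci_low, ci_high):
    exposures = np.asarray(exposures, float)
    lo, hi = np.asarray(ci_low, float), np.asarray(ci_high, float)
    return AttributionResult(
        sample_id=sample,
        panel_names=list(names),
        exposures=exposures,
        ci_low=lo,
        ci_high=hi,
        l2_similarity=0.9,
        presence=(lo > 0) & (hi > 0),
        total=int(exposures.sum()),
        unassigned=0.0,
    )


class TestDichotomize:
    def test_ci_presence_rule(self):
        # CI (0, 40) -> absent; CI (5, 40) -> present
        results = AttributionResults(
            panel_names=["sigA"],
            results=[
                _attr_result("s1", ["sigA"], [30], [0], [40]),
                _attr_result("s2", ["sigA"], [30], [5], [40]),
                _attr_result("s3", ["sigA"], [10], [0], [20]),
            ],
        )
        out = dichotomize(results)
        assert out.loc["s1", "sigA"] == 0
        assert out.loc["s2", "sigA"] == 1

    def test_median_split_for_ubiquitous_signature(self, rng):
        n = 40
        exposures = rng.integers(100, 5000, n)
        results = AttributionResults(
            panel_names=["ubi"],
            results=[
                _attr_result(
                    f"s{i}", ["ubi"], [exposures[i]],
                    [exposures[i] * 0.5 if i < 36 else 0], [exposures[i] * 1.5],
                )
                for i in range(n)
            ],
        )
        out = dichotomize(results)  # prevalence 90% >= 75% -> median split
        frac = out["ubi"].mean()
        assert 0.4 <= frac <= 0.6


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_step_up_closed_form_random(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 15))
            order = np.argsort(p)
            m = len(p)
            q_sorted = np.minimum.accumulate(
                (m * p[order] / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1)
            assert np.allclose(bh_adjust(p), expected)

    def test_permutation_invariance(self, rng):
        p = rng.random(10)
        perm = rng.permutation(10)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def enumeration_wilcoxon_p(d):
    """Exact two-sided p by full enumeration of the 2^n sign assignments."""
    d = np.asarray(d, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    tot = ranks.sum()
    lo, hi = min(w_obs, tot - w_obs), max(w_obs, tot - w_obs)
    ws = [
        sum(r for s, r in zip(signs, ranks) if s > 0)
        for signs in itertools.product([1, -1], repeat=len(d))
    ]
    ws = np.array(ws)
    return float(((ws <= lo) | (ws >= hi)).mean())


class TestWilcoxon:
    def test_all_zero_differences(self):
        r = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert r.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        # distinct magnitudes: the exact null assumes untied ranks
        mags = rng.choice(np.arange(1, 50), size=n, replace=False)
        d = mags * rng.choice([-1.0, 1.0], size=n) + rng.random(n) * 0.01
        r = wilcoxon_signed_rank(d)
        assert r.p_value == pytest.approx(enumeration_wilcoxon_p(d))

    def test_paired_interface(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.5, 2.5, 1.0, 3.0, 4.0])
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            enumeration_wilcoxon_p(x - y)
        )


class TestFisher:
    def test_hypergeometric_closed_form(self):
        """Two-sided Fisher p equals the sum of hypergeometric point masses
        no larger than the observed table's."""
        a, b, c, d = 25, 75, 13, 87
        r = fisher_exact_2x2([[a, b], [c, d]])
        N, K, n = a + b + c + d, a + c, a + b
        pmf = [stats.hypergeom.pmf(k, N, K, n) for k in range(K + 1)]
        obs = stats.hypergeom.pmf(a, N, K, n)
        expected = sum(p for p in pmf if p <= obs * (1 + 1e-9))
        assert r.p_value == pytest.approx(expected, rel=1e-6)

    def test_identical_proportions_maximal_p(self):
        assert fisher_exact_2x2([[10, 90], [10, 90]]).p_value == 1.0

    def test_extreme_table_closed_form_tail(self):
        # all target-class mutations in one group: single-tail hypergeometric
        r = fisher_exact_2x2([[5, 5], [0, 10]])
        p_tail = stats.hypergeom.pmf(5, 20, 5, 10)
        assert r.p_value >= p_tail
        assert r.p_value == pytest.approx(
            sum(
                stats.hypergeom.pmf(k, 20, 5, 10)
                for k in range(6)
                if stats.hypergeom.pmf(k, 20, 5, 10)
                <= stats.hypergeom.pmf(5, 20, 5, 10) * (1 + 1e-9)
            )
        )


def make_cohort(rng, n=300):
    return pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], n),
            "age_dx": rng.normal(62, 10, n),
            "country": rng.choice(["A", "B", "C"], n),
            "smoking": rng.choice(["current", "ex", "never"], n),
        }
    )


class TestRegressions:
    def test_planted_effect_recovered(self, rng):
        n = 500
        df = make_cohort(rng, n)
        is_current = (df["smoking"] == "current").to_numpy()
        p = 1 / (1 + np.exp(-(-1.0 + np.log(3) * is_current)))
        df["outcome"] = (rng.random(n) < p).astype(int)
        df["smoking_current"] = is_current.astype(int)
        r = risk_factor_regression(
            df, "outcome", "smoking_current",
            covariates=("sex", "age_dx", "country"),
        )
        assert r.estimate > 0
        assert r.p_value < 0.05

    def test_constant_factor_rejected(self, rng):
        df = make_cohort(rng, 50)
        df["outcome"] = rng.integers(0, 2, 50)
        df["factor"] = 1.0
        with pytest.raises(ValueError):
            risk_factor_regression(df, "outcome", "factor")

    def test_family_size_recorded_not_applied(self, rng):
        df = make_cohort(rng, 200)
        df["outcome"] = rng.integers(0, 2, 200)
        df["x"] = rng.normal(size=200)
        r = risk_factor_regression(df, "outcome", "x", family_size=224)
        assert r.family_size == 224
        assert 0 <= r.p_value <= 1

    def test_asr_slope_recovered(self, rng):
        n = 400
        asr = rng.choice([1.8, 4.5, 7.6, 10.3, 14.4], n)
        df = pd.DataFrame(
            {
                "asr": asr,
                "y": 1500 + 150 * asr + rng.normal(0, 700, n),
                "sex": rng.choice(["male", "female"], n),
                "age_dx": rng.normal(62, 10, n),
            }
        )
        r = asr_regression(df, "y")
        se = abs(r.estimate - 150) / 150
        assert r.estimate > 0 and r.p_value < 1e-6
        assert se < 0.5

    def test_single_country_asr_rejected(self, rng):
        df = pd.DataFrame({"asr": [5.0] * 20, "y": rng.normal(size=20)})
        with pytest.raises(ValueError):
            asr_regression(df, "y")

    def test_collinear_response(self, rng):
        asr = rng.choice([1.8, 4.5, 7.6, 10.3], 100)
        df = pd.DataFrame({"asr": asr, "y": asr})
        assert asr_regression(df, "y", covariates=()).p_value < 1e-12


class TestCountryBurden:
    def test_shifted_country_detected(self, rng):
        burdens = pd.Series(
            np.concatenate([rng.lognormal(8, 0.5, 30) * (5 if g == 0 else 1)
                            for g in range(3)])
        )
        countries = pd.Series(["X"] * 30 + ["Y"] * 30 + ["Z"] * 30)
        assert country_burden_test(burdens, countries).p_value < 0.001

    def test_single_country_rejected(self, rng):
        burdens = pd.Series(rng.lognormal(8, 0.5, 30))
        with pytest.raises(ValueError):
            country_burden_test(burdens, pd.Series(["X"] * 30))

    def test_small_countries_excluded(self, rng):
        burdens = pd.Series(rng.lognormal(8, 0.5, 41))
        countries = pd.Series(["X"] * 20 + ["Y"] * 20 + ["Z"])
        r = country_burden_test(burdens, countries)
        assert r.n == 40


def cluster_row(sample, cid, ccf, n, chrom="1", clonal=False):
    return {
        "sample_id": sample, "cluster_id": cid, "ccf": ccf,
        "n_mutations": n, "top_chrom": chrom, "clonal": clonal,
    }


class TestTimingFilters:
    def base_clusters(self, sample="s1"):
        return [
            cluster_row(sample, "clone", 1.0, 600, clonal=True),
            cluster_row(sample, "sub", 0.5, 400),
        ]

    def test_clean_sample_retained(self):
        df = pd.DataFrame(self.base_clusters())
        kept, excl = filter_timing_samples(df, pd.Series({"s1": 0.8}))
        assert excl == {}
        assert set(kept["sample_id"]) == {"s1"}

    def test_low_purity_excluded(self):
        df = pd.DataFrame(self.base_clusters())
        _, excl = filter_timing_samples(df, pd.Series({"s1": 0.3}))
        assert excl == {"s1": "purity"}

    def test_high_ccf_cluster_dropped_sample_kept(self):
        rows = self.base_clusters() + [cluster_row("s1", "art", 1.6, 300)]
        kept, excl = filter_timing_samples(
            pd.DataFrame(rows), pd.Series({"s1": 0.8})
        )
        assert excl == {}
        assert "art" not in set(kept["cluster_id"])

    def test_chrx_dominant_cluster_dropped(self):
        rows = self.base_clusters() + [cluster_row("s1", "xart", 0.4, 300, chrom="X")]
        kept, _ = filter_timing_samples(pd.DataFrame(rows), pd.Series({"s1": 0.8}))
        assert "xart" not in set(kept["cluster_id"])

    def test_mutation_floor(self):
        rows = [
            cluster_row("s1", "clone", 1.0, 200, clonal=True),  # below 256
            cluster_row("s1", "sub", 0.5, 400),
        ]
        _, excl = filter_timing_samples(pd.DataFrame(rows), pd.Series({"s1": 0.9}))
        assert excl == {"s1": "min_mutations"}

    def test_poorly_separated_subclone(self):
        rows = [
            cluster_row("s1", "clone", 1.0, 600, clonal=True),
            cluster_row("s1", "sub", 0.85, 400),
        ]
        _, excl = filter_timing_samples(pd.DataFrame(rows), pd.Series({"s1": 0.9}))
        assert excl == {"s1": "subclone_separation"}

    def test_filters_toggleable_and_counts_sum(self):
        rows = (
            self.base_clusters("ok")
            + [
                cluster_row("lowp", "clone", 1.0, 600, clonal=True),
                cluster_row("lowp", "sub", 0.5, 400),
                cluster_row("small", "clone", 1.0, 100, clonal=True),
                cluster_row("small", "sub", 0.5, 400),
            ]
        )
        purity = pd.Series({"ok": 0.9, "lowp": 0.2, "small": 0.9})
        kept, excl = filter_timing_samples(pd.DataFrame(rows), purity)
        n_in = 3
        assert len(set(kept["sample_id"])) + len(excl) == n_in
        # disabling both rules retains everything
        kept2, excl2 = filter_timing_samples(
            pd.DataFrame(rows), purity, min_purity=None, min_mutations=None
        )
        assert excl2 == {}
        assert len(set(kept2["sample_id"])) == 3


class TestClonalSubclonalEnrichment:
    def test_identical_mixes_give_p_one(self, sigs3, rng):
        spectra = {
            f"s{i}": rng.multinomial(2000, sigs3.profiles @ [0.3, 0.2, 0.5])
            for i in range(6)
        }
        channels = list(SBS96.channels)
        cat = CatalogueMatrix(
            SBS96, list(spectra), np.column_stack(list(spectra.values()))
        )
        out = clonal_subclonal_enrichment(cat, cat, sigs3, PenaltyConfig(n_boot=1))
        assert (out["p_value"] == 1.0).all()
        assert (out["clonal_mean"] == out["subclonal_mean"]).all()

    def test_planted_enrichment_detected(self, sigs3, rng):
        n = 30
        clonal_cols, sub_cols, ids = [], [], []
        for i in range(n):
            ids.append(f"s{i}")
            clonal_cols.append(
                rng.multinomial(3000, sigs3.profiles @ [0.4, 0.0, 0.6])
            )
            sub_cols.append(
                rng.multinomial(1500, sigs3.profiles @ [0.2, 0.0, 0.8])
            )
        clonal = CatalogueMatrix(SBS96, ids, np.column_stack(clonal_cols))
        sub = CatalogueMatrix(SBS96, ids, np.column_stack(sub_cols))
        out = clonal_subclonal_enrichment(clonal, sub, sigs3)
        row = out[out["signature"] == "S_TA"].iloc[0]
        assert row.clonal_mean > row.subclonal_mean
        assert row.q_value < 0.05


class TestDriverEnrichment:
    def test_identical_proportions(self):
        classes = pd.Series(["T>A"] * 10 + ["C>T"] * 40 + ["T>A"] * 10 + ["C>T"] * 40)
        exposed = pd.Series([True] * 50 + [False] * 50)
        props, r = driver_spectrum_enrichment(classes, exposed)
        assert r.p_value == 1.0
        assert props[f"prop_T>A"].tolist() == [0.2, 0.2]

    def test_empty_group_rejected(self):
        classes = pd.Series(["T>A", "C>T"])
        with pytest.raises(ValueError):
            driver_spectrum_enrichment(classes, pd.Series([True, True]))
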