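"""Colocalization posteriors against a brute-force enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from targetmr import (
    RegionDataset,
    coloc_flags,
    coloc_posteriors,
    estimate_sdY,
    generate_region_panel,
    region_window,
)
from targetmr.coloc import DEFAULT_PRIORS, wakefield_labf


def brute_force_posteriors(l1, l2, priors=DEFAULT_PRIORS):
    """Enumerate all (m+1)^2 single-causal configurations in plain space.

    Configuration (i, j) with i, j in {none, 1..m}: the prior weight is 1 for
    (none, none), p1*ABF1_i for (i, none), p2*ABF2_j for (none, j),
    p1*p2*ABF1_i*ABF2_j for distinct (i, j), and p12*ABF1_i*ABF2_i for i = j.
    """
    p1, p2, p12 = priors
    a1, a2 = np.exp(l1), np.exp(l2)
    m = len(a1)
    h = np.zeros(5)
    h[0] = 1.0
    for i in range(m):
        h[1] += p1 * a1[i]
        h[2] += p2 * a2[i]
        for j in range(m):
            if i == j:
                h[4] += p12 * a1[i] * a2[i]
            else:
                h[3] += p1 * p2 * a1[i] * a2[j]
    return h / h.sum()


def _random_region(rng, m, z_scale=2.0):
    maf = rng.uniform(0.05, 0.5, m)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * 50_000)
    beta = rng.standard_normal(m) * se * z_scale
    df = pd.DataFrame(
        {"variant_id": [f"v{i}" for i in range(m)], "pos": np.arange(m) * 1000,
         "maf": maf, "beta": beta, "se": se}
    )
    return RegionDataset(df=df, trait_type="quant", n=50_000, sdY=1.0)


class TestEnumerationOracle:
    @pytest.mark.parametrize("m", [1, 2, 7, 20])
    def test_posteriors_match_brute_force(self, m):
        rng = np.random.default_rng(m)
        d1, d2 = _random_region(rng, m), _random_region(rng, m)
        res = coloc_posteriors(d1, d2)
        l1 = wakefield_labf(d1.df["beta"], d1.df["se"], 0.15)
        l2 = wakefield_labf(d2.df["beta"], d2.df["se"], 0.15)
        expected = brute_force_posteriors(l1, l2)
        got = np.array([res[f"pp_h{k}"] for k in range(5)])
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_posteriors_sum_to_one_and_permutation_invariant(self):
        rng = np.random.default_rng(42)
        d1, d2 = _random_region(rng, 15), _random_region(rng, 15)
        res = coloc_posteriors(d1, d2)
        total = sum(res[f"pp_h{k}"] for k in range(5))
        assert total == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(15)
        d1p = RegionDataset(df=d1.df.iloc[perm].reset_index(drop=True), trait_type="quant",
                            n=d1.n, sdY=1.0)
        d2p = RegionDataset(df=d2.df.iloc[perm].reset_index(drop=True), trait_type="quant",
                            n=d2.n, sdY=1.0)
        resp = coloc_posteriors(d1p, d2p)
        for k in range(5):
            assert resp[f"pp_h{k}"] == pytest.approx(res[f"pp_h{k}"], abs=1e-12)


class TestRegionPanels:
    def test_shared_causal_panel_colocalizes(self):
        d1, d2 = generate_region_panel(shared_causal=True, n_variants=100, seed=1,
                                       peak_z1=10, peak_z2=9)
        res = coloc_posteriors(d1, d2)
        assert res["pp_h4"] > 0.8

    def test_distinct_peaks_favor_h3(self):
        d1, d2 = generate_region_panel(shared_causal=False, n_variants=100, seed=2,
                                       peak_z1=10, peak_z2=9)
        res = coloc_posteriors(d1, d2)
        assert res["pp_h3"] > res["pp_h4"]

    def test_null_panel_favors_h0(self):
        d1, d2 = generate_region_panel(shared_causal=True, n_variants=100, seed=3,
                                       peak_z1=0.0, peak_z2=0.0)
        res = coloc_posteriors(d1, d2)
        assert res["pp_h0"] > 0.5

    def test_strong_signals_colocalize_reliably_across_seeds(self):
        strong = 0
        h3_wins = 0
        for seed in range(50):
            d1, d2 = generate_region_panel(shared_causal=True, n_variants=80,
                                           seed=seed, peak_z1=10, peak_z2=9)
            strong += coloc_posteriors(d1, d2)["strong"]
            e1, e2 = generate_region_panel(shared_causal=False, n_variants=80,
                                           seed=seed, peak_z1=10, peak_z2=9)
            r = coloc_posteriors(e1, e2)
            h3_wins += r["pp_h3"] > r["pp_h4"]
        assert strong / 50 > 0.9
        assert h3_wins / 50 > 0.9


class TestRegionWindow:
    def _frames(self, positions, mafs):
        df = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(len(positions))],
             "pos": positions, "maf": mafs}
        )
        return df

    def test_inclusive_boundary_and_strict_maf(self):
        d = self._frames([750_000, 1_250_000, 1_250_001, 1_000_000], [0.2, 0.2, 0.2, 0.01])
        f1, f2 = region_window(1_000_000, d, d.copy())
        kept = set(f1["variant_id"])
        assert "v0" in kept and "v1" in kept  # exactly +/- 250 kb retained
        assert "v2" not in kept  # one bp outside
        assert "v3" not in kept  # MAF exactly 1% excluded (strict >)

    def test_disjoint_variant_sets_give_empty_intersection(self):
        a = self._frames([1_000_000], [0.2])
        b = self._frames([1_000_000], [0.2])
        b["variant_id"] = ["other"]
        f1, f2 = region_window(1_000_000, a, b)
        assert f1.empty and f2.empty


class TestSdY:
    def test_recovers_unit_trait_sd(self):
        rng = np.random.default_rng(9)
        maf = rng.uniform(0.05, 0.5, 500)
        n = 20_000
        se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n) * rng.uniform(0.98, 1.02, 500)
        assert estimate_sdY(se, maf, n) == pytest.approx(1.0, rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        maf = rng.uniform(0.05, 0.5, 100)
        se = 1.0 / np.sqrt(2 * maf * (1 - maf) * 10_000)
        base = estimate_sdY(se, maf, 10_000)
        assert estimate_sdY(3.0 * se, maf, 10_000) == pytest.approx(3.0 * base, rel=1e-9)

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError):
            estimate_sdY([0.01], [0.3], 1000)


class TestColocFlags:
    def test_any_and_all_flags(self):
        assert coloc_flags([{"strong": True}, {"strong": False}]) == {
            "any_strong": True, "all_strong": False,
        }
        assert coloc_flags([{"strong": True}, {"strong": True}]) == {
            "any_strong": True, "all_strong": True,
        }

    def test_missing_results_distinct_from_false(self):
        flags = coloc_flags([])
        assert flags["any_strong"] is None and flags["all_strong"] is None


def test_case_control_route_uses_pvalues_and_case_fraction():
    """A cc dataset specified via p-values yields a proper posterior."""
    rng = np.random.default_rng(21)
    m = 40
    maf = rng.uniform(0.05, 0.5, m)
    n = 50_000
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n * 0.25)
    beta = rng.standard_normal(m) * se
    beta[m // 2] = 8 * se[m // 2]
    from scipy import stats

    pv = 2 * stats.norm.sf(np.abs(beta / se))
    df = pd.DataFrame({"variant_id": [f"v{i}" for i in range(m)], "pos": np.arange(m),
                       "maf": maf, "pval": pv, "beta": np.sign(beta)})
    cc = RegionDataset(df=df, trait_type="cc", n=n, case_fraction=0.5)
    quant = RegionDataset(
        df=pd.DataFrame({"variant_id": df["variant_id"], "pos": df["pos"], "maf": maf,
                         "beta": beta, "se": se}),
        trait_type="quant", n=n, sdY=1.0,
    )
    res = coloc_posteriors(quant, cc)
    assert sum(res[f"pp_h{k}"] for k in range(5)) == pytest.approx(1.0, abs=1e-9)
    assert res["pp_h4"] > 0.5
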