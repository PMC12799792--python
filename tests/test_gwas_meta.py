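"""Fixed-effect meta-analysis, genomic control, and trait harmonization."""

import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetmr import (
    gc_correct,
    genomic_lambda,
    map_traits,
    meta_all,
    meta_fixed_ivw,
    underflow_floor,
)


class TestMetaFixedIvw:
    def test_identical_cohorts_shrink_se_only(self):
        res = meta_fixed_ivw([0.3, 0.3], [0.1, 0.1])
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))
        assert res.q_stat == pytest.approx(0.0)

    def test_hand_worked_heterogeneous_pair(self):
        # w1 = w2 = 100; beta = 0.4; Q = 100*(0.2^2 + 0.2^2) = 8 on 1 df
        res = meta_fixed_ivw([0.2, 0.6], [0.1, 0.1])
        assert res.beta == pytest.approx(0.4)
        assert res.se == pytest.approx(0.070710678, rel=1e-6)
        assert res.q_stat == pytest.approx(8.0)
        assert res.q_pval == pytest.approx(stats.chi2.sf(8.0, 1))

    def test_single_cohort_passthrough(self):
        res = meta_fixed_ivw([0.25], [0.05])
        assert res.beta == pytest.approx(0.25)
        assert res.se == pytest.approx(0.05)
        assert res.q_stat is None and res.q_pval is None

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_k_identical_cohorts_shrink_by_sqrt_k(self, k):
        res = meta_fixed_ivw([0.3] * k, [0.1] * k)
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / np.sqrt(k))

    def test_q_invariant_to_cohort_order(self):
        rng = np.random.default_rng(0)
        betas, ses = rng.normal(0.2, 0.1, 5), rng.uniform(0.05, 0.2, 5)
        a = meta_fixed_ivw(betas, ses)
        perm = rng.permutation(5)
        b = meta_fixed_ivw(betas[perm], ses[perm])
        assert a.beta == pytest.approx(b.beta)
        assert a.q_stat == pytest.approx(b.q_stat)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed_ivw([0.1, 0.2], [0.1, 0.0])


class TestUnderflowFloor:
    def test_zero_becomes_smallest_normal_float(self):
        assert underflow_floor(0.0) == sys.float_info.min
        assert underflow_floor(0.0) == pytest.approx(2.2250738585072014e-308)

    def test_small_and_unit_values_unchanged(self):
        assert underflow_floor(1e-30) == 1e-30
        assert underflow_floor(1.0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            underflow_floor(-0.1)


class TestGenomicLambda:
    def test_constant_half_pvalues_give_unity(self):
        assert genomic_lambda(np.full(1000, 0.5)) == pytest.approx(1.0)

    def test_uniform_null_is_calibrated(self):
        rng = np.random.default_rng(1)
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert 0.98 < lam < 1.02

    def test_recovers_known_inflation(self):
        rng = np.random.default_rng(2)
        chi = rng.chisquare(1, 100_000) * 1.3
        pv = stats.chi2.sf(chi, 1)
        assert genomic_lambda(pv) == pytest.approx(1.3, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda([])


class TestGcCorrect:
    def _records(self, z, se=0.05):
        return pd.DataFrame({"beta": [z * se], "se": [se]})

    def test_lambda_one_is_identity(self):
        rec = self._records(4.0)
        out = gc_correct(rec, 1.0)
        assert out["se"].iloc[0] == pytest.approx(rec["se"].iloc[0])

    def test_z4_lambda4_halves_z(self):
        out = gc_correct(self._records(4.0), 4.0)
        z = out["beta"].iloc[0] / out["se"].iloc[0]
        assert z == pytest.approx(2.0)
        assert out["pval"].iloc[0] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_correction_recalibrates_lambda(self):
        rng = np.random.default_rng(3)
        n = 50_000
        se = np.full(n, 0.05)
        beta = rng.standard_normal(n) * se * np.sqrt(1.4)
        rec = pd.DataFrame({"beta": beta, "se": se})
        rec["pval"] = 2 * stats.norm.sf(np.abs(beta) / se)
        lam = genomic_lambda(rec["pval"])
        corrected = gc_correct(rec, lam)
        assert genomic_lambda(corrected["pval"]) == pytest.approx(1.0, abs=0.02)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            gc_correct(self._records(1.0), 0.0)


class TestMapTraits:
    def _mapping(self):
        return pd.DataFrame(
            {
                "cohort": ["a", "b", "c"],
                "code": ["a:x", "b:x", "c:x"],
                "trait": ["T1", "T1", "T1"],
                "provenance": ["direct"] * 3,
            }
        )

    def _tables(self):
        return {
            c: pd.DataFrame({"trait_code": [f"{c}:x"], "beta": [0.1]}) for c in "abc"
        }

    def test_three_cohorts_share_canonical_trait(self):
        out = map_traits(self._mapping(), self._tables())
        assert all(df["trait"].iloc[0] == "T1" for df in out.values())

    def test_unmapped_code_retained_as_single_cohort_trait(self):
        tables = self._tables()
        tables["a"] = pd.DataFrame({"trait_code": ["a:orphan"], "beta": [0.2]})
        out = map_traits(self._mapping(), tables)
        assert out["a"]["trait"].iloc[0] == "a:orphan"

    def test_conflicting_duplicate_mapping_rejected(self):
        bad = pd.concat(
            [self._mapping(), pd.DataFrame([{"cohort": "a", "code": "a:x", "trait": "T2",
                                             "provenance": "manual"}])]
        )
        with pytest.raises(ValueError):
            map_traits(bad, self._tables())


class TestMetaAll:
    def test_matches_scalar_meta_with_allele_flips(self):
        """Vectorized meta equals per-variant IVW after allele alignment."""
        rec = {
            "variant_id": "rs9", "chrom": "1", "pos": 100, "trait": "T1",
            "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
            "beta": 0.12, "se": 0.05, "pval": 0.016, "n": 1000, "n_cases": np.nan,
        }
        flipped = {**rec, "effect_allele": "G", "other_allele": "A",
                   "beta": -0.08, "eaf": 0.7}
        strand = {**rec, "effect_allele": "T", "other_allele": "C", "beta": 0.10}
        frames = {
            "c0": pd.DataFrame([rec]),
            "c1": pd.DataFrame([flipped]),
            "c2": pd.DataFrame([strand]),
        }
        out = meta_all(frames)
        assert len(out) == 1
        expected = meta_fixed_ivw([0.12, 0.08, 0.10], [0.05] * 3)
        assert out["beta"].iloc[0] == pytest.approx(expected.beta)
        assert out["se"].iloc[0] == pytest.approx(expected.se)
        assert out["q_stat"].iloc[0] == pytest.approx(expected.q_stat)
        assert out["k"].iloc[0] == 3
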