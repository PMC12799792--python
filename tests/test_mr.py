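"""Harmonization and the Wald/IVW/MR-Egger estimators against WLS oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from targetmr import bonferroni_threshold, harmonize, ivw, mr_all, mr_egger, wald_ratio
from conftest import random_mr_fixture


def _pair_frames(exp_alleles, out_alleles, beta_out=0.05, eaf_exp=0.3, eaf_out=None):
    exp = pd.DataFrame(
        [{
            "variant_id": "rs1", "effect_allele": exp_alleles[0],
            "other_allele": exp_alleles[1], "beta": 0.10, "se": 0.01,
            "eaf": eaf_exp, "gene": "g1",
        }]
    )
    out = pd.DataFrame(
        [{
            "variant_id": "rs1", "effect_allele": out_alleles[0],
            "other_allele": out_alleles[1], "beta": beta_out, "se": 0.02,
            "eaf": eaf_exp if eaf_out is None else eaf_out,
        }]
    )
    return exp, out


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp, out = _pair_frames(("A", "G"), ("G", "A"), beta_out=-0.05)
        h = harmonize(exp, out)
        assert h["action"].iloc[0] == "flip"
        assert h["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_strand_complement_match_retained(self):
        exp, out = _pair_frames(("C", "T"), ("G", "A"), beta_out=0.05, eaf_out=0.20)
        h = harmonize(exp, out)
        assert h["action"].iloc[0] == "strand-flip"
        assert h["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_ambiguous_palindromic_dropped(self):
        exp, out = _pair_frames(("A", "T"), ("A", "T"), eaf_exp=0.5, eaf_out=0.50)
        h = harmonize(exp, out)
        assert h.empty

    def test_unambiguous_palindromic_oriented_by_frequency(self):
        exp, out = _pair_frames(("A", "T"), ("A", "T"), beta_out=-0.05,
                                eaf_exp=0.2, eaf_out=0.8)
        h = harmonize(exp, out)
        assert h["action"].iloc[0] == "flip"
        assert h["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_incompatible_allele_sets_dropped(self):
        exp, out = _pair_frames(("A", "G"), ("A", "C"))
        assert harmonize(exp, out).empty


class TestWaldRatio:
    def test_hand_worked_delta_method(self):
        res = wald_ratio(0.25, 0.01, 0.5, 0.1)
        assert res["beta"] == pytest.approx(2.0)
        assert res["se"] == pytest.approx(0.4)

    def test_null_outcome_gives_unit_p(self):
        res = wald_ratio(0.2, 0.01, 0.0, 0.1)
        assert res["beta"] == 0.0
        assert res["pval"] == pytest.approx(1.0)

    @pytest.mark.parametrize("bx,by", [(0.2, 0.1), (-0.2, 0.1), (0.2, -0.1), (-0.2, -0.1)])
    def test_sign_is_product_of_signs(self, bx, by):
        res = wald_ratio(bx, 0.01, by, 0.05)
        assert np.sign(res["beta"]) == np.sign(bx) * np.sign(by)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


class TestIvw:
    def test_collinear_ratios_recovered_exactly(self):
        res = ivw([1.0, 2.0], [0.01, 0.01], [0.5, 1.0], [0.1, 0.2])
        assert res["beta"] == pytest.approx(0.5)
        assert res["q_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_through_origin_oracle(self):
        """200 random fixtures: IVW equals zero-intercept WLS to 1e-10."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            k = rng.integers(2, 9)
            bx, sx, by, sy = random_mr_fixture(rng, k)
            res = ivw(bx, sx, by, sy)
            fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            assert abs(res["beta"] - fit.params[0]) < 1e-10

    def test_equals_inverse_variance_mean_of_wald_ratios(self):
        rng = np.random.default_rng(12)
        bx, sx, by, sy = random_mr_fixture(rng, 6)
        res = ivw(bx, sx, by, sy)
        ratios = by / bx
        w = (bx / sy) ** 2
        assert res["beta"] == pytest.approx(np.sum(w * ratios) / np.sum(w), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        bx, sx, by, sy = random_mr_fixture(rng, 5)
        a = ivw(bx, sx, by, sy)
        p = rng.permutation(5)
        b = ivw(bx[p], sx[p], by[p], sy[p])
        for key in ("beta", "se", "pval", "q_stat"):
            assert a[key] == pytest.approx(b[key], rel=1e-12)

    def test_mre_mode_never_shrinks_se(self):
        rng = np.random.default_rng(14)
        bx, sx, by, sy = random_mr_fixture(rng, 6)
        fe = ivw(bx, sx, by, sy, mode="fe")
        mre = ivw(bx, sx, by, sy, mode="mre")
        assert mre["se"] >= fe["se"]
        assert mre["beta"] == pytest.approx(fe["beta"])


class TestMrEgger:
    def test_collinear_points_through_origin(self):
        bx = np.array([1.0, 2.0, 3.0])
        res = mr_egger(bx, bx * 0 + 0.01, 0.5 * bx, [0.1, 0.1, 0.1])
        assert res["egger_intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["beta"] == pytest.approx(0.5)

    def test_matches_wls_oracle(self):
        """200 random fixtures: slope and intercept equal free-intercept WLS."""
        rng = np.random.default_rng(15)
        for _ in range(200):
            k = rng.integers(3, 10)
            bx, sx, by, sy = random_mr_fixture(rng, k)
            res = mr_egger(bx, sx, by, sy)
            sgn = np.where(bx < 0, -1.0, 1.0)
            ax, ay = bx * sgn, by * sgn
            fit = sm.WLS(ay, sm.add_constant(ax), weights=1.0 / sy**2).fit()
            assert abs(res["beta"] - fit.params[1]) < 1e-10
            assert abs(res["egger_intercept"] - fit.params[0]) < 1e-10

    def test_recovers_planted_pleiotropy_intercept(self):
        rng = np.random.default_rng(16)
        k = 50
        bx = rng.uniform(0.05, 0.3, k)
        sy = np.full(k, 0.02)
        by = 0.1 + 0.5 * bx + rng.normal(0, sy)
        res = mr_egger(bx, np.full(k, 0.01), by, sy)
        assert abs(res["egger_intercept"] - 0.1) < 3 * res["egger_intercept_se"]

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.02])


class TestBonferroni:
    def test_study_scale_threshold_rounds_to_printed_value(self):
        thr = bonferroni_threshold(0.05, 31_525_236)
        assert thr == pytest.approx(1.586e-9, rel=1e-3)
        assert float(f"{thr:.1e}") == 1.6e-9

    def test_trivial_cases(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)


class TestMrAllVectorized:
    def test_matches_per_group_estimators(self):
        """The grouped closed-form path equals wald/ivw/egger per group."""
        rng = np.random.default_rng(17)
        frames = []
        for gi in range(30):
            k = rng.integers(1, 7)
            bx, sx, by, sy = random_mr_fixture(rng, k)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": f"g{gi}", "trait": "T1", "source": "decode",
                        "tissue": None, "beta_exp": bx, "se_exp": sx,
                        "beta_out": by, "se_out": sy,
                    }
                )
            )
        tall = pd.concat(frames, ignore_index=True)
        res = mr_all(tall).set_index("gene")
        for gi in range(30):
            grp = tall[tall["gene"] == f"g{gi}"]
            row = res.loc[f"g{gi}"]
            bx, sx = grp["beta_exp"].to_numpy(), grp["se_exp"].to_numpy()
            by, sy = grp["beta_out"].to_numpy(), grp["se_out"].to_numpy()
            if len(grp) == 1:
                ref = wald_ratio(bx[0], sx[0], by[0], sy[0])
                assert row["method"] == "wald"
            else:
                ref = ivw(bx, sx, by, sy)
                assert row["method"] == "ivw"
                assert row["q_stat"] == pytest.approx(ref["q_stat"], abs=1e-10)
            assert row["beta"] == pytest.approx(ref["beta"], rel=1e-10)
            assert row["se"] == pytest.approx(ref["se"], rel=1e-10)
            if len(grp) >= 3:
                egger = mr_egger(bx, sx, by, sy)
                assert row["egger_beta"] == pytest.approx(egger["beta"], rel=1e-9)
                assert row["egger_intercept"] == pytest.approx(
                    egger["egger_intercept"], rel=1e-9, abs=1e-12
                )
                assert row["egger_intercept_pval"] == pytest.approx(
                    egger["egger_intercept_pval"], rel=1e-9
                )
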