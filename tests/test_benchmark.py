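"""Benchmark construction, matched controls, logistic enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetmr import build_benchmark, enrichment_or, matched_nonselected
from targetmr.drug_annot import dedupe_target_indications


def _target_indications(n_pos=5):
    rows = []
    for i in range(n_pos):
        rows.append(
            {
                "drug_id": f"d{i}", "target_gene": f"P{i}", "max_phase": 4,
                "indication_label": f"disease {i}", "indication_code": f"EFO:{i}",
                "indication_parent": "parent", "moa": "inhibitor",
            }
        )
    return dedupe_target_indications(pd.DataFrame(rows))


def _traits(n=5):
    return pd.DataFrame(
        {
            "trait": [f"T{i}" for i in range(n)],
            "label": [f"disease {i}" for i in range(n)],
            "code": [f"EFO:{i}" for i in range(n)],
            "parents": ["parent"] * n,
        }
    )


class TestBuildBenchmark:
    def test_ten_negatives_per_positive(self):
        universe = [f"G{i}" for i in range(40)] + [f"P{i}" for i in range(5)]
        bench = build_benchmark(_target_indications(), _traits(), universe, seed=1)
        assert (bench["label"] == "positive").sum() == 5
        assert (bench["label"] == "negative").sum() == 50
        per_pos = bench[bench["label"] == "negative"].groupby("matched_positive").size()
        assert (per_pos == 10).all()

    def test_negative_gene_never_equals_its_positives_gene(self):
        universe = [f"G{i}" for i in range(40)] + [f"P{i}" for i in range(5)]
        bench = build_benchmark(_target_indications(), _traits(), universe, seed=1)
        pos = bench[bench["label"] == "positive"].set_index("benchmark_id")
        for _, row in bench[bench["label"] == "negative"].iterrows():
            assert row["gene"] != pos.loc[row["matched_positive"], "gene"]

    def test_negatives_share_their_positives_trait(self):
        universe = [f"G{i}" for i in range(40)]
        bench = build_benchmark(_target_indications(), _traits(), universe, seed=1)
        pos = bench[bench["label"] == "positive"].set_index("benchmark_id")
        neg = bench[bench["label"] == "negative"]
        assert (neg["trait"].to_numpy() == pos.loc[neg["matched_positive"], "trait"].to_numpy()).all()

    def test_seed_determinism(self):
        universe = [f"G{i}" for i in range(40)]
        a = build_benchmark(_target_indications(), _traits(), universe, seed=3)
        b = build_benchmark(_target_indications(), _traits(), universe, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_small_universe_emits_fewer_with_warning(self):
        universe = [f"G{i}" for i in range(4)]
        with pytest.warns(UserWarning):
            bench = build_benchmark(_target_indications(1), _traits(1), universe, seed=1)
        assert (bench["label"] == "negative").sum() == 4


class TestMatchedNonselected:
    def _results(self, rng, n_genes=60, n_traits=6):
        rows = []
        sources = ["gtex", "eqtlgen", "decode", "fenland", "aric"]
        probs = [0.35, 0.25, 0.2, 0.1, 0.1]
        for g in range(n_genes):
            for t in range(n_traits):
                k = rng.integers(1, 5)
                for s in rng.choice(sources, size=k, replace=False, p=probs):
                    rows.append({"gene": f"G{g}", "trait": f"T{t}", "source": s,
                                 "pval": rng.uniform()})
        return pd.DataFrame(rows)

    def test_one_control_per_selected_with_matching_source_count(self):
        rng = np.random.default_rng(8)
        results = self._results(rng)
        counts = results.groupby(["gene", "trait"])["source"].nunique()
        selected = counts.sample(20, random_state=1).reset_index()[["gene", "trait"]]
        controls = matched_nonselected(selected, results, seed=2)
        assert len(controls) == len(selected)
        merged = controls.merge(
            counts.rename("ctrl_n").reset_index(), on=["gene", "trait"]
        )
        assert (merged["ctrl_n"] == merged["n_sources"]).all()

    def test_controls_disjoint_from_selected(self):
        rng = np.random.default_rng(9)
        results = self._results(rng)
        counts = results.groupby(["gene", "trait"])["source"].nunique()
        selected = counts.sample(15, random_state=2).reset_index()[["gene", "trait"]]
        controls = matched_nonselected(selected, results, seed=3)
        sel = set(map(tuple, selected.to_numpy()))
        ctl = set(map(tuple, controls[["gene", "trait"]].to_numpy()))
        assert not sel & ctl

    def test_control_source_marginal_tracks_empirical_distribution(self):
        """Sampled control sources follow the tested-set source frequencies."""
        rng = np.random.default_rng(10)
        results = self._results(rng, n_genes=120, n_traits=8)
        counts = results.groupby(["gene", "trait"])["source"].nunique()
        singles = counts[counts == 1]
        selected = singles.sample(min(len(singles), 200), random_state=3).reset_index()[
            ["gene", "trait"]
        ]
        controls = matched_nonselected(selected, results, seed=5)
        drawn = controls["control_sources"].str.split(";").explode()
        freq = results["source"].value_counts(normalize=True)
        obs = drawn.value_counts().reindex(freq.index).fillna(0).to_numpy()
        chi2, p = stats.chisquare(obs, freq.to_numpy() * obs.sum())
        assert p > 0.01


class TestEnrichmentOr:
    def test_univariate_or_equals_cross_product_ratio(self):
        y = np.concatenate([np.ones(100), np.zeros(100)])
        f = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
        out = enrichment_or(y, pd.DataFrame({"f": f}))
        assert out["odds_ratio"].iloc[0] == pytest.approx((30 * 90) / (70 * 10), rel=1e-5)

    def test_independent_feature_gives_unit_or(self):
        y = np.concatenate([np.ones(100), np.zeros(100)])
        f = np.tile([1.0, 0.0], 100)
        out = enrichment_or(y, pd.DataFrame({"f": f}))
        assert out["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_perfectly_predictive_feature_flagged_separated(self):
        y = np.concatenate([np.ones(50), np.zeros(50)])
        out = enrichment_or(y, pd.DataFrame({"f": y.copy()}), continuity_correction=True)
        assert out["separated"].iloc[0]
        assert np.isfinite(out["odds_ratio"].iloc[0])

    def test_multivariable_adjustment_runs(self):
        rng = np.random.default_rng(12)
        n = 400
        f1 = rng.integers(0, 2, n).astype(float)
        f2 = rng.integers(0, 2, n).astype(float)
        logit = -1 + 1.2 * f1 + 0.1 * f2
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        out = enrichment_or(y, pd.DataFrame({"f1": f1, "f2": f2}))
        assert len(out) == 2
        assert out.set_index("feature").loc["f1", "odds_ratio"] > 1.5

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            enrichment_or(np.ones(10), pd.DataFrame({"f": np.zeros(10)}))

    def test_enrichment_or_increases_with_evidence_rate(self):
        """Higher causal-pair evidence coverage yields larger estimated ORs."""
        from targetmr import SimConfig, generate_world

        ors = []
        for rate in (0.05, 0.3, 0.7):
            w = generate_world(
                SimConfig(n_traits=8, n_genes=80, seed=21, frac_causal=0.1,
                          evidence_rate_causal=rate, evidence_rate_null=0.02,
                          n_approved_pairs=20, n_dev_pairs=5)
            )
            causal = w.causal_pairs()
            pairs = w.truth[["gene", "trait"]]
            covered = set()
            for df in w.evidence.values():
                covered |= set(map(tuple, df[["gene", "trait"]].to_numpy()))
            y = np.array([1.0 if p in causal else 0.0 for p in map(tuple, pairs.to_numpy())])
            f = np.array([1.0 if p in covered else 0.0 for p in map(tuple, pairs.to_numpy())])
            out = enrichment_or(y, pd.DataFrame({"ev": f}), continuity_correction=True)
            ors.append(out["odds_ratio"].iloc[0])
        assert ors[0] < ors[1] < ors[2]
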