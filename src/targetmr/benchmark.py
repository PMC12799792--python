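"""Benchmark construction and feature-enrichment statistics.

Positive controls are approved (phase-4) drug target-indication pairs mapped
to traits with genetic summary statistics.  Each positive is matched with 10
negative controls sharing its indication/trait (so GWAS power is balanced
within a stratum), with genes drawn from the universe of genes having at
least one significant MR result.  A separate matched set pairs each selected
MR gene-trait with a non-selected result carrying the same number of QTL
sources, for logistic-regression enrichment of orthogonal features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["build_benchmark", "matched_nonselected", "enrichment_or"]

NEGATIVES_PER_POSITIVE = 10


def map_indications_to_traits(
    target_indications: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Attach a genetic trait to each approved target-indication.

    Mapping is by exact ontology code first; indications without a coded
    trait fall back to the lexicographically smallest trait sharing their
    parent term.  Unmappable indications are dropped.
    """
    by_code = dict(zip(traits["code"], traits["trait"]))
    by_parent = (
        traits.sort_values("trait").groupby("parents")["trait"].first().to_dict()
    )
    rows = []
    for _, row in target_indications.iterrows():
        trait = by_code.get(row["indication_code"])
        if trait is None:
            trait = by_parent.get(row["indication_parent"])
        if trait is None:
            continue
        rows.append({**row.to_dict(), "trait": trait})
    return pd.DataFrame(rows)


def build_benchmark(
    target_indications: pd.DataFrame,
    traits: pd.DataFrame,
    significant_genes: list[str],
    seed: int,
    n_negatives: int = NEGATIVES_PER_POSITIVE,
) -> pd.DataFrame:
    """Positive/negative benchmark rows for the ranking model.

    Positives are approved target-indications mapped to traits; for each, 10
    negatives are sampled without replacement from ``significant_genes``
    (genes with at least one genome-wide-significant MR result), excluding
    any gene forming a positive with the same indication.  When the eligible
    universe is smaller than requested, fewer negatives are emitted with a
    warning rather than sampling with replacement.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    mapped = map_indications_to_traits(
        target_indications[target_indications["max_phase"] == 4], traits
    )
    if mapped.empty:
        raise ValueError("no approved target-indication could be mapped to a trait")
    mapped = mapped.sort_values(["target_gene", "canonical_code"]).reset_index(drop=True)
    universe = np.array(sorted(set(significant_genes)))
    pos_genes_by_trait = mapped.groupby("trait")["target_gene"].apply(set).to_dict()
    rows = []
    import warnings

    for i, row in mapped.iterrows():
        pid = f"P{i:04d}"
        rows.append(
            {
                "benchmark_id": pid,
                "gene": row["target_gene"],
                "trait": row["trait"],
                "label": "positive",
                "matched_positive": None,
            }
        )
        excluded = pos_genes_by_trait[row["trait"]]
        eligible = universe[~np.isin(universe, sorted(excluded))]
        take = min(n_negatives, eligible.size)
        if take < n_negatives:
            warnings.warn(
                f"only {take} eligible negative genes for positive {pid}", stacklevel=2
            )
        for g in rng.choice(eligible, size=take, replace=False):
            rows.append(
                {
                    "benchmark_id": f"{pid}:neg",
                    "gene": g,
                    "trait": row["trait"],
                    "label": "negative",
                    "matched_positive": pid,
                }
            )
    return pd.DataFrame(rows)


def matched_nonselected(
    selected: pd.DataFrame,
    all_results: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """One non-selected control per selected pair, matched on source count.

    Controls are drawn from gene-traits without a selected result, matched on
    the number of QTL sources available, with the control's source identities
    sampled by the empirical source distribution of the full tested set.
    """
    rng = np.random.default_rng(seed)
    counts = all_results.groupby(["gene", "trait"])["source"].agg(["nunique"])
    counts.columns = ["n_sources"]
    sel_keys = set(map(tuple, selected[["gene", "trait"]].to_numpy()))
    pool = counts[~counts.index.isin(sel_keys)]
    source_freq = all_results["source"].value_counts(normalize=True)
    rows = []
    for gene, trait in sorted(sel_keys):
        n_src = counts.loc[(gene, trait), "n_sources"] if (gene, trait) in counts.index else 1
        stratum = pool[pool["n_sources"] == n_src]
        if stratum.empty:
            stratum = pool  # exhausted stratum: resample from the full pool
        pick = stratum.index[rng.integers(0, len(stratum))]
        sources = rng.choice(
            source_freq.index.to_numpy(), size=int(n_src), replace=False,
            p=source_freq.to_numpy(),
        ) if n_src <= len(source_freq) else source_freq.index.to_numpy()
        rows.append(
            {
                "gene": pick[0],
                "trait": pick[1],
                "matched_gene": gene,
                "matched_trait": trait,
                "n_sources": int(n_src),
                "control_sources": ";".join(sorted(map(str, sources))),
            }
        )
    return pd.DataFrame(rows)


def enrichment_or(
    labels,
    features,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Logistic-regression enrichment of features in cases vs controls.

    ``labels`` is a binary outcome (selected vs not, or positive vs negative
    control); ``features`` a binary Series (univariate) or a DataFrame
    (multivariable, all features adjusted simultaneously).  Reports per
    feature the odds ratio, Wald 95% CI and p.  Complete separation (a zero
    cell in the univariate 2x2 table) is flagged; with
    ``continuity_correction`` the univariate OR is then recomputed from the
    0.5-corrected table.
    """
    y = np.asarray(labels, dtype=float)
    X = pd.DataFrame(features).astype(float)
    if y.size != len(X):
        raise ValueError("labels and features must align")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome levels must be present")
    rows = []
    separated_cols = set()
    for col in X.columns:
        f = X[col].to_numpy()
        if set(np.unique(f)) <= {0.0, 1.0}:
            cells = np.array(
                [
                    np.sum((y == 1) & (f == 1)),
                    np.sum((y == 1) & (f == 0)),
                    np.sum((y == 0) & (f == 1)),
                    np.sum((y == 0) & (f == 0)),
                ]
            )
            if (cells == 0).any():
                separated_cols.add(col)
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        _warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            params, bse, pvals = fit.params, fit.bse, fit.pvalues
        except Exception:  # perfect separation can break the MLE outright
            params = pd.Series(np.nan, index=["const", *X.columns])
            bse = pd.Series(np.nan, index=["const", *X.columns])
            pvals = pd.Series(np.nan, index=["const", *X.columns])
    for col in X.columns:
        coef, se, p = params[col], bse[col], pvals[col]
        separated = col in separated_cols
        with np.errstate(over="ignore"):
            or_, lo, hi = np.exp(coef), np.exp(coef - 1.96 * se), np.exp(coef + 1.96 * se)
        f = X[col].to_numpy()
        binary = set(np.unique(f)) <= {0.0, 1.0}
        degenerate = not (np.isfinite(or_) and np.isfinite(se) and se < 50)
        if binary and continuity_correction and (separated or degenerate):
            a = np.sum((y == 1) & (f == 1)) + 0.5
            b = np.sum((y == 1) & (f == 0)) + 0.5
            c = np.sum((y == 0) & (f == 1)) + 0.5
            d = np.sum((y == 0) & (f == 0)) + 0.5
            or_ = (a * d) / (b * c)
            lse = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            lo, hi = or_ * np.exp(-1.96 * lse), or_ * np.exp(1.96 * lse)
            z = abs(np.log(or_)) / lse
            from scipy import stats as _stats

            p = 2.0 * _stats.norm.sf(z)
        rows.append(
            {
                "feature": col,
                "odds_ratio": float(or_),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "pval": float(p) if np.isfinite(p) else np.nan,
                "separated": bool(separated),
                "n": int(y.size),
            }
        )
    return pd.DataFrame(rows)
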