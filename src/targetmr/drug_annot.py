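"""Mapping selected gene-traits onto a drug catalog.

Selected MR pairs are compared with a catalog of drug target-indication
records.  A pair whose gene is the target of an approved (phase-4) drug and
whose trait matches an approved indication is a *rediscovery*; a match to a
phase 1-3 program is a *development-match*; an approved target with no
indication matching the trait is a *repurposing* opportunity when the MR
direction predicts benefit under the drug's mechanism of action (MoA), or a
*safety-flag* when it predicts harm.  Traits are oriented so a positive MR
beta means the exposure raises disease risk: an inhibitor of a risk-raising
target is beneficial, an activator harmful, and vice versa.

MoA concordance over rediscoveries — how often the MR direction predicts the
approved mechanism — is summarized with an exact binomial test against 0.5
and a Clopper-Pearson interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phenomap import TermIndex, match

__all__ = ["dedupe_target_indications", "classify", "classify_all", "moa_concordance"]

_SCHEMES = ("exact", "parent", "distance")


def dedupe_target_indications(catalog: pd.DataFrame) -> pd.DataFrame:
    """Collapse a drug catalog into unique (target, indication) pairs.

    Indications of the same target that share an ontology code are one pair;
    indications sharing only a parent term are merged onto the
    lexicographically smallest member's code (exact-or-parent identity).  The
    pair's phase is the maximum over contributing drugs, and the MoA set of
    contributing drugs is kept.  Rows without a target gene are dropped.
    """
    df = catalog.dropna(subset=["target_gene"]).copy()
    merged_code = {}
    for target, grp in df.groupby("target_gene"):
        by_parent = grp.sort_values("indication_code").groupby("indication_parent")
        for _, pgrp in by_parent:
            canonical = pgrp["indication_code"].min()
            for code in pgrp["indication_code"].unique():
                merged_code[(target, code)] = canonical
    df["canonical_code"] = [
        merged_code[(t, c)] for t, c in zip(df["target_gene"], df["indication_code"])
    ]
    rep = df.sort_values("indication_code").groupby(
        ["target_gene", "canonical_code"], as_index=False
    ).agg(
        max_phase=("max_phase", "max"),
        indication_label=("indication_label", "first"),
        indication_code=("indication_code", "first"),
        indication_parent=("indication_parent", "first"),
        moas=("moa", lambda s: sorted(set(s))),
        drugs=("drug_id", lambda s: sorted(set(s))),
    )
    return rep


def _trait_term(traits: pd.DataFrame, trait: str) -> dict:
    row = traits.loc[traits["trait"] == trait].iloc[0]
    return {
        "label": row["label"],
        "code": row["code"],
        "parents": row["parents"],
        "source_group": "genetic-phenotypes",
    }


def _indication_term(row) -> dict:
    return {
        "label": row["indication_label"],
        "code": row["indication_code"],
        "parents": row["indication_parent"],
        "source_group": "drug-indications",
    }


def _match_scheme(trait_term, indication_term, index: TermIndex | None) -> str | None:
    """Most specific scheme under which two terms match, or None."""
    for scheme in _SCHEMES:
        if scheme == "distance" and index is None:
            continue
        if match(trait_term, indication_term, scheme, index=index):
            return scheme
    return None


def classify(
    gene: str,
    trait: str,
    mr_beta: float,
    target_indications: pd.DataFrame,
    traits: pd.DataFrame,
    index: TermIndex | None = None,
) -> dict:
    """Translational call for one selected gene-trait pair.

    Returns a dict with ``call`` in {rediscovery, development-match,
    repurposing, safety-flag, none}, the matched indication and scheme where
    applicable, and ``moa_concordant`` for rediscoveries with a directional
    MoA.
    """
    entries = target_indications[target_indications["target_gene"] == gene]
    base = {"gene": gene, "trait": trait, "call": "none", "matched_indication": None,
            "scheme": None, "moa_concordant": None}
    if entries.empty:
        return base
    tterm = _trait_term(traits, trait)
    best = None  # (priority, scheme, row)
    for _, row in entries.iterrows():
        scheme = _match_scheme(tterm, _indication_term(row), index)
        if scheme is None:
            continue
        priority = (0 if row["max_phase"] == 4 else 1, _SCHEMES.index(scheme))
        if best is None or priority < best[0]:
            best = (priority, scheme, row)
    if best is not None:
        _, scheme, row = best
        if row["max_phase"] == 4:
            moas = set(row["moas"]) - {"other"}
            concordant = None
            if moas:
                expected = "inhibitor" if mr_beta > 0 else "activator"
                concordant = expected in moas
            return {**base, "call": "rediscovery", "matched_indication": row["indication_label"],
                    "scheme": scheme, "moa_concordant": concordant}
        return {**base, "call": "development-match",
                "matched_indication": row["indication_label"], "scheme": scheme}
    approved = entries[entries["max_phase"] == 4]
    if approved.empty:
        return base
    # approved target, unmatched trait: direction of MR beta under the
    # approved MoA decides benefit (repurposing) vs harm (safety flag)
    moas = set().union(*approved["moas"]) - {"other"}
    if not moas:
        return {**base, "call": "repurposing"}
    beneficial = ("inhibitor" in moas and mr_beta > 0) or ("activator" in moas and mr_beta < 0)
    return {**base, "call": "repurposing" if beneficial else "safety-flag"}


def classify_all(
    selected: pd.DataFrame,
    target_indications: pd.DataFrame,
    traits: pd.DataFrame,
    index: TermIndex | None = None,
) -> pd.DataFrame:
    """Classify every selected gene-trait pair (one call per pair)."""
    calls = [
        classify(row["gene"], row["trait"], row["rep_beta"], target_indications, traits, index)
        for _, row in selected.iterrows()
    ]
    return pd.DataFrame(calls)


def moa_concordance(calls: pd.DataFrame) -> dict:
    """Fraction of rediscoveries whose MR direction predicts the approved MoA.

    Only rediscoveries with a directional MoA (activator or inhibitor) enter
    the denominator.  Reports the point estimate, exact Clopper-Pearson 95%
    CI, and the exact binomial p-value against 0.5.
    """
    redis = calls[(calls["call"] == "rediscovery") & calls["moa_concordant"].notna()]
    n = len(redis)
    if n == 0:
        raise ValueError("no rediscoveries with a directional MoA")
    k = int(redis["moa_concordant"].sum())
    test = stats.binomtest(k, n, 0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return {
        "n": n,
        "n_concordant": k,
        "fraction": k / n,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "pval": float(test.pvalue),
    }
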