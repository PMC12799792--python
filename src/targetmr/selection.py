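"""Rule-based concordance selection of gene-trait pairs across QTL sources.

Each gene-trait pair may carry several MR estimates — one per instrument
source, and one per tissue for the tissue-resolved eQTL panel.  Sources are
never meta-analyzed; instead significant results are screened by direction:

1. a pair significant in a single source is accepted as-is;
2. when both eQTL and pQTL sources are significant, direction is checked only
   among the pQTL sources (post-transcriptional regulation can legitimately
   decouple transcript and protein effects), and the pQTL layer is carried
   forward;
3. when only eQTL sources are significant, all of them (including every
   significant tissue) must agree in sign;
4. any sign disagreement within the governing set excludes the pair.

The representative estimate carried downstream is the minimum-p result within
the governing layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import EQTL_SOURCES, PQTL_SOURCES

__all__ = ["SelectionDecision", "decide", "decide_all", "summarize_selection"]


@dataclass
class SelectionDecision:
    gene: str
    trait: str
    verdict: str  # accepted | excluded-discordant | not-significant
    layer: str | None = None  # pqtl | eqtl
    representative: dict | None = None
    significant_sources: list = field(default_factory=list)


def _primary_pval(row) -> float:
    return row["pval"]


def decide(results: pd.DataFrame, threshold: float) -> SelectionDecision:
    """Apply the concordance rules to all MR results of one gene-trait pair.

    ``results`` holds one row per source(-tissue) with at least columns
    (gene, trait, source, tissue, beta, pval).  Significance is judged on the
    primary method's p-value (Wald/IVW; Egger is sensitivity-only).  Exact
    zero betas carry no direction and abstain from the concordance vote.
    """
    if results.empty:
        raise ValueError("decide() needs at least the gene/trait identifiers")
    gene = results["gene"].iloc[0]
    trait = results["trait"].iloc[0]
    sig = results[results["pval"] <= threshold]
    if sig.empty:
        return SelectionDecision(gene, trait, "not-significant")
    sig_sources = [
        (r["source"], r.get("tissue"), int(np.sign(r["beta"])), r["pval"])
        for _, r in sig.iterrows()
    ]
    pqtl_sig = sig[sig["source"].isin(PQTL_SOURCES)]
    governing = pqtl_sig if not pqtl_sig.empty else sig
    layer = "pqtl" if not pqtl_sig.empty else "eqtl"
    signs = set(np.sign(governing["beta"][governing["beta"] != 0]).astype(int))
    if len(signs) > 1:
        return SelectionDecision(
            gene, trait, "excluded-discordant", layer=layer, significant_sources=sig_sources
        )
    rep = governing.sort_values(
        ["pval", "source", "tissue"], kind="mergesort", na_position="last"
    ).iloc[0]
    return SelectionDecision(
        gene,
        trait,
        "accepted",
        layer=layer,
        representative=rep.to_dict(),
        significant_sources=sig_sources,
    )


def decide_all(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Vectorized selection over an MR results table.

    Only gene-traits with at least one significant result need the rule
    machinery; the rest are counted as not-significant without materializing
    per-pair frames.  Returns one row per significant gene-trait with columns
    (gene, trait, verdict, layer, n_sig_sources) plus the representative
    estimate's fields prefixed ``rep_``.
    """
    sig = results[results["pval"] <= threshold]
    rows = []
    for (gene, trait), grp in sig.groupby(["gene", "trait"], sort=False):
        pq = grp[grp["source"].isin(PQTL_SOURCES)]
        governing = pq if not pq.empty else grp
        layer = "pqtl" if not pq.empty else "eqtl"
        nonzero = governing["beta"][governing["beta"] != 0]
        discordant = nonzero.size > 0 and (nonzero > 0).any() and (nonzero < 0).any()
        row = {
            "gene": gene,
            "trait": trait,
            "layer": layer,
            "n_sig_sources": len(grp),
            "verdict": "excluded-discordant" if discordant else "accepted",
        }
        if not discordant:
            rep = governing.sort_values(
                ["pval", "source", "tissue"], kind="mergesort", na_position="last"
            ).iloc[0]
            for key in ("source", "tissue", "method", "beta", "se", "pval", "n_iv",
                        "q_stat", "q_pval", "egger_intercept", "egger_intercept_pval"):
                if key in rep.index:
                    row[f"rep_{key}"] = rep[key]
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["gene", "trait", "layer", "n_sig_sources", "verdict"]
        )
    return pd.DataFrame(rows)


def summarize_selection(decisions: pd.DataFrame, n_tested: int | None = None) -> dict:
    """Aggregate selection counts: tested, significant, excluded, selected."""
    selected = int((decisions["verdict"] == "accepted").sum())
    excluded = int((decisions["verdict"] == "excluded-discordant").sum())
    acc = decisions[decisions["verdict"] == "accepted"]
    return {
        "tested": int(n_tested) if n_tested is not None else None,
        "significant_any": selected + excluded,
        "excluded_discordant": excluded,
        "selected": selected,
        "unique_genes": int(acc["gene"].nunique()),
        "unique_traits": int(acc["trait"].nunique()),
    }
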