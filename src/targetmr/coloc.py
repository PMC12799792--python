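"""Approximate-Bayes-factor colocalization of QTL and GWAS signals.

For each instrument, variants within a ±250 kb window and with MAF > 1% are
intersected between the QTL and outcome datasets, per-variant Wakefield log
approximate Bayes factors are computed for both, and posterior probabilities
for the five single-causal-variant hypotheses are obtained by enumeration:

H0 no association; H1/H2 association in one dataset only; H3 two distinct
causal variants; H4 one shared causal variant.  PP.H4 > 0.8 flags strong
colocalization.  All accumulation is in log space (log-sum-exp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "RegionDataset",
    "region_window",
    "estimate_sdY",
    "wakefield_labf",
    "coloc_posteriors",
    "coloc_flags",
    "DEFAULT_PRIORS",
]

#: Default single-variant priors (p1, p2, p12), the conventional coloc values.
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

#: Wakefield prior effect SDs: per-sdY for quantitative traits, log-odds for
#: case-control.  Conventional defaults; configurable per call.
SD_PRIOR_QUANT = 0.15
SD_PRIOR_CC = 0.2

WINDOW_BP = 250_000
MAF_MIN = 0.01


@dataclass
class RegionDataset:
    """Per-variant summary statistics for one trait in one genomic region.

    ``df`` needs columns (variant_id, pos, maf) plus either (beta, se) or
    (pval) — the latter is converted internally using maf and n.  ``sdY`` may
    be given for quantitative traits; when absent it is estimated from the
    summary statistics.
    """

    df: pd.DataFrame
    trait_type: str = "quant"  # "quant" | "cc"
    n: float = 0.0
    sdY: float | None = None
    case_fraction: float | None = None

    def __post_init__(self):
        if self.trait_type not in ("quant", "cc"):
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if len(self.df) < 1:
            raise ValueError("a region needs at least one variant")
        if self.trait_type == "cc" and self.case_fraction is None:
            raise ValueError("case-control datasets need a case fraction")


def region_window(
    instrument_pos: int,
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    window: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two region tables to the coloc window and intersect them.

    Variants with |pos - instrument_pos| <= window (inclusive boundary) and
    MAF strictly above ``maf_min`` are retained, then the two tables are
    intersected on variant id.  Returns a pair of aligned frames; both empty
    when the intersection is empty.
    """

    def _filter(df):
        keep = (np.abs(df["pos"] - instrument_pos) <= window) & (df["maf"] > maf_min)
        return df[keep]

    f1, f2 = _filter(d1), _filter(d2)
    shared = f1.merge(f2[["variant_id"]], on="variant_id", how="inner")["variant_id"]
    f1 = f1[f1["variant_id"].isin(shared)].sort_values("variant_id", kind="mergesort")
    f2 = f2[f2["variant_id"].isin(shared)].sort_values("variant_id", kind="mergesort")
    return f1.reset_index(drop=True), f2.reset_index(drop=True)


def estimate_sdY(se, maf, n) -> float:
    """Estimate a quantitative trait's SD from summary statistics.

    Under the standard approximation var(beta_hat) ~ sdY^2 / (2 maf (1-maf) n),
    regressing 1/se^2 on 2 maf (1-maf) n through the origin yields a slope of
    1/sdY^2; sdY is the square root of its reciprocal.
    """
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if se.size < 2:
        raise ValueError("sdY estimation needs at least two variants")
    x = 2.0 * maf * (1.0 - maf) * n
    y = 1.0 / se**2
    slope = float(np.sum(x * y) / np.sum(x * x))
    if slope <= 0:
        raise ValueError("non-positive sdY estimate; region rejected")
    return float(np.sqrt(1.0 / slope))


def _beta_se_from_region(d: RegionDataset) -> tuple[np.ndarray, np.ndarray]:
    from scipy import stats

    df = d.df
    if "beta" in df.columns and "se" in df.columns and df["se"].notna().all():
        return df["beta"].to_numpy(float), df["se"].to_numpy(float)
    # p-value route: reconstruct |z| and an SE from maf/n (and case fraction)
    z = stats.norm.isf(np.clip(df["pval"].to_numpy(float), 1e-300, 1.0) / 2.0)
    maf = df["maf"].to_numpy(float)
    if d.trait_type == "cc":
        s = d.case_fraction
        v = 1.0 / (2.0 * maf * (1.0 - maf) * d.n * s * (1.0 - s))
    else:
        sdY = d.sdY if d.sdY is not None else 1.0
        v = sdY**2 / (2.0 * maf * (1.0 - maf) * d.n)
    se = np.sqrt(v)
    sign = df["beta"].to_numpy(float) if "beta" in df.columns else np.ones_like(se)
    return np.sign(sign) * z * se, se


def wakefield_labf(beta, se, sd_prior: float) -> np.ndarray:
    """Per-variant Wakefield log approximate Bayes factor.

    With V = se^2, W = sd_prior^2, z = beta/se:
    log ABF = 0.5 * (log(V / (V + W)) + z^2 * W / (V + W)).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    v = se**2
    w = sd_prior**2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + z2 * r)


def _labf_for(d: RegionDataset, sd_prior_quant: float, sd_prior_cc: float) -> np.ndarray:
    beta, se = _beta_se_from_region(d)
    if d.trait_type == "cc":
        sd_prior = sd_prior_cc
    else:
        sdY = d.sdY
        if sdY is None:
            sdY = estimate_sdY(se, d.df["maf"].to_numpy(float), d.n)
        sd_prior = sd_prior_quant * sdY
    return wakefield_labf(beta, se, sd_prior)


def coloc_posteriors(
    d1: RegionDataset,
    d2: RegionDataset,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    sd_prior_quant: float = SD_PRIOR_QUANT,
    sd_prior_cc: float = SD_PRIOR_CC,
) -> dict:
    """Posterior probabilities of the five colocalization hypotheses.

    The two datasets must carry the same variants in the same order.  Returns
    ``pp_h0`` … ``pp_h4`` (summing to one), the number of variants used, and
    ``strong`` = PP.H4 > 0.8.
    """
    if len(d1.df) != len(d2.df) or not (
        d1.df["variant_id"].to_numpy() == d2.df["variant_id"].to_numpy()
    ).all():
        raise ValueError("datasets must share an aligned variant list")
    l1 = _labf_for(d1, sd_prior_quant, sd_prior_cc)
    l2 = _labf_for(d2, sd_prior_quant, sd_prior_cc)
    p1, p2, p12 = priors
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(p1) + s1
    lh2 = np.log(p2) + s2
    # sum over i != j of ABF1_i ABF2_j = exp(s1)exp(s2) - exp(s12)
    both = s1 + s2
    if len(l1) > 1 and s12 < both:
        lh3 = np.log(p1) + np.log(p2) + both + np.log1p(-np.exp(s12 - both))
    else:
        lh3 = -np.inf
    lh4 = np.log(p12) + s12
    lse = logsumexp([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(np.array([lh0, lh1, lh2, lh3, lh4]) - lse)
    return {
        "pp_h0": float(pp[0]),
        "pp_h1": float(pp[1]),
        "pp_h2": float(pp[2]),
        "pp_h3": float(pp[3]),
        "pp_h4": float(pp[4]),
        "n_variants_used": int(len(l1)),
        "strong": bool(pp[4] > 0.8),
    }


def coloc_flags(results: list[dict]) -> dict:
    """Summarize per-instrument coloc results for one gene-trait pair.

    ``any_strong`` — strong colocalization at one or more instruments;
    ``all_strong`` — at every instrument.  With no results both flags are
    missing (None), which is distinct from False.
    """
    if not results:
        return {"any_strong": None, "all_strong": None}
    strongs = [bool(r["strong"]) for r in results]
    return {"any_strong": any(strongs), "all_strong": all(strongs)}
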