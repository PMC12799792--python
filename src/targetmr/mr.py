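"""Two-sample Mendelian randomization estimators.

Exposure (QTL) and outcome (GWAS) summary statistics are aligned to a common
effect allele, then causal effects are estimated by the Wald ratio (single
instrument), inverse-variance-weighted regression through the origin (IVW,
multiple instruments) and MR-Egger regression with a free intercept as a
pleiotropy sensitivity analysis (three or more instruments).  Cochran's Q over
the per-variant Wald ratios quantifies heterogeneity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "bonferroni_threshold",
    "mr_all",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: Outcome allele-frequency window in which a palindromic variant is ambiguous.
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return (ea.map(_COMPLEMENT) == oa).fillna(False)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
    keep_outcome_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Align outcome alleles to the exposure's effect allele.

    Matched on ``variant_id``.  Swapped alleles flip the outcome beta and
    complement its frequency; strand-complemented alleles are mapped through
    the base-complement table first.  Palindromic (A/T, C/G) variants whose
    outcome frequency falls in ``palindromic_window`` are dropped as
    strand-ambiguous; palindromic variants outside the window are oriented by
    frequency concordance.  Unresolvable allele sets are dropped.

    Returns one row per retained variant with columns ``beta_exp, se_exp,
    beta_out, se_out, eaf, action`` where action is one of none / flip /
    strand-flip / dropped-palindromic / dropped-incompatible.
    """
    exp = exposure.rename(
        columns={"beta": "beta_exp", "se": "se_exp", "eaf": "eaf_exp",
                 "effect_allele": "ea_exp", "other_allele": "oa_exp"}
    )
    out = outcome.rename(
        columns={"beta": "beta_out", "se": "se_out", "eaf": "eaf_out",
                 "effect_allele": "ea_out", "other_allele": "oa_out"}
    )
    keep_exp = [c for c in exp.columns if c not in ("pval", "n")]
    out_cols = ["variant_id", "ea_out", "oa_out", "beta_out", "se_out", "eaf_out"]
    out_cols += [c for c in keep_outcome_cols if c in out.columns]
    merged = exp[keep_exp].merge(out[out_cols], on="variant_id", how="inner")
    if merged.empty:
        return merged.assign(action=pd.Series(dtype=object))

    ea_e, oa_e = merged["ea_exp"], merged["oa_exp"]
    ea_o, oa_o = merged["ea_out"], merged["oa_out"]
    missing = ea_e.isna() | oa_e.isna() | ea_o.isna() | oa_o.isna()
    pal = _is_palindromic(ea_e, oa_e) & ~missing

    same = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    cea, coa = ea_o.map(_COMPLEMENT), oa_o.map(_COMPLEMENT)
    strand = (cea == ea_e) & (coa == oa_e) & ~pal
    strand_swapped = (cea == oa_e) & (coa == ea_e) & ~pal

    lo, hi = palindromic_window
    pal_ambiguous = pal & merged["eaf_out"].between(lo, hi)
    # unambiguous palindromic variants: allele strings always "match"; orient
    # by which side of 0.5 the frequencies fall on
    pal_flip = pal & ~pal_ambiguous & (
        np.sign(merged["eaf_out"] - 0.5) != np.sign(merged["eaf_exp"] - 0.5)
    )

    action = pd.Series("dropped-incompatible", index=merged.index, dtype=object)
    action[same & ~pal] = "none"
    action[swapped & ~same & ~pal] = "flip"
    action[strand] = "strand-flip"
    action[strand_swapped & ~strand] = "flip"
    action[pal & ~pal_ambiguous & ~pal_flip] = "none"
    action[pal_flip] = "flip"
    action[pal_ambiguous] = "dropped-palindromic"
    action[missing] = "dropped-incompatible"

    flip_mask = action == "flip"
    merged.loc[flip_mask, "beta_out"] = -merged.loc[flip_mask, "beta_out"]
    merged.loc[flip_mask, "eaf_out"] = 1.0 - merged.loc[flip_mask, "eaf_out"]
    merged["action"] = action
    retained = merged[~action.str.startswith("dropped")].copy()
    retained["eaf"] = retained["eaf_exp"]
    drop_cols = ["ea_out", "oa_out", "eaf_out"]
    return retained.drop(columns=[c for c in drop_cols if c in retained.columns]).reset_index(drop=True)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> dict:
    """Single-instrument Wald ratio with first-order (delta-method) SE.

    beta = beta_out / beta_exp; se = se_out / |beta_exp|; two-sided normal p.
    """
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for a zero exposure effect")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return {"method": "wald", "beta": float(beta), "se": float(se), "pval": p, "n_iv": 1}


def ivw(beta_exp, se_exp, beta_out, se_out, mode: str = "fe") -> dict:
    """Inverse-variance-weighted MR over multiple instruments.

    Zero-intercept regression of outcome on exposure effects with weights
    ``1/se_out^2`` — algebraically the inverse-variance mean of the per-variant
    Wald ratios.  ``mode="fe"`` (default) uses the analytic fixed-effect SE;
    ``mode="mre"`` applies the multiplicative random-effects convention,
    scaling the SE by ``max(1, sqrt(Q/(k-1)))``.  Cochran's Q is computed over
    the Wald ratios in either mode.
    """
    bx = np.asarray(beta_exp, dtype=float)
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    k = bx.size
    if k < 2:
        raise ValueError("IVW requires at least two instruments; use wald_ratio")
    if np.any(bx == 0):
        raise ValueError("IVW requires nonzero exposure effects")
    if mode not in ("fe", "mre"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    w = 1.0 / sy**2
    swxx = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / swxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    se = float(1.0 / np.sqrt(swxx))
    if mode == "mre":
        se *= float(np.sqrt(max(1.0, q / (k - 1))))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    q_p = float(stats.chi2.sf(q, k - 1))
    return {
        "method": "ivw",
        "beta": beta,
        "se": se,
        "pval": p,
        "n_iv": int(k),
        "q_stat": q,
        "q_pval": q_p,
    }


def mr_egger(beta_exp, se_exp, beta_out, se_out) -> dict:
    """MR-Egger: weighted regression with a free intercept.

    Pairs are oriented so all exposure effects are non-negative (flipping the
    sign of both members of a pair), then outcome effects are regressed on
    exposure effects with weights ``1/se_out^2``.  A nonzero intercept signals
    directional pleiotropy.  SEs follow the conventional multiplicative
    random-effects floor, with p-values from a t distribution on k - 2 df.
    """
    bx = np.asarray(beta_exp, dtype=float).copy()
    by = np.asarray(beta_out, dtype=float).copy()
    sy = np.asarray(se_out, dtype=float)
    k = bx.size
    if k < 3:
        raise ValueError("MR-Egger requires at least three instruments")
    sgn = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sgn, by * sgn
    w = 1.0 / sy**2
    sw, sx, sy_ = np.sum(w), np.sum(w * bx), np.sum(w * by)
    sxx, sxy = np.sum(w * bx**2), np.sum(w * bx * by)
    denom = sw * sxx - sx**2
    if denom <= 0:
        raise ValueError("degenerate design: exposure effects are constant")
    slope = (sw * sxy - sx * sy_) / denom
    intercept = (sy_ - slope * sx) / sw
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    infl = max(1.0, sigma2)
    se_slope = float(np.sqrt(sw / denom * infl))
    se_int = float(np.sqrt(sxx / denom * infl))
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, k - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, k - 2))
    return {
        "method": "egger",
        "beta": float(slope),
        "se": se_slope,
        "pval": p_slope,
        "n_iv": int(k),
        "egger_intercept": float(intercept),
        "egger_intercept_se": se_int,
        "egger_intercept_pval": p_int,
    }


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold: alpha divided by the test count."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def mr_all(
    harmonized: pd.DataFrame,
    group_cols: list[str] | None = None,
    ivw_mode: str = "fe",
) -> pd.DataFrame:
    """Grouped MR over a harmonized exposure/outcome table.

    One result row per group: the Wald ratio where a group has a single
    instrument, IVW where it has two or more (with Cochran's Q), and MR-Egger
    columns filled in for groups of three or more.  Implemented with grouped
    closed-form sums so hundreds of thousands of gene-trait-source units run
    in seconds; unit tests pin this path to the per-group estimators above.
    """
    if group_cols is None:
        group_cols = ["gene", "trait", "source", "tissue"]
    df = harmonized[harmonized["beta_exp"] != 0].copy()
    bx, by, sy = df["beta_exp"], df["beta_out"], df["se_out"]
    w = 1.0 / sy**2
    df["_w"] = w
    df["_wxx"] = w * bx**2
    df["_wxy"] = w * bx * by
    df["_wyy"] = w * by**2
    # Egger orientation: all exposure effects non-negative
    sgn = np.where(bx < 0, -1.0, 1.0)
    ax, ay = bx * sgn, by * sgn
    df["_wx"] = w * ax
    df["_wy"] = w * ay
    g = df.groupby(group_cols, sort=False, dropna=False)
    agg = g.agg(
        n_iv=("_w", "size"),
        sw=("_w", "sum"),
        swxx=("_wxx", "sum"),
        swxy=("_wxy", "sum"),
        swyy=("_wyy", "sum"),
        swx=("_wx", "sum"),
        swy=("_wy", "sum"),
    )
    first = g.agg(beta_exp=("beta_exp", "first"), se_exp=("se_exp", "first"),
                  beta_out=("beta_out", "first"), se_out=("se_out", "first"))

    k = agg["n_iv"].to_numpy(dtype=float)
    beta = (agg["swxy"] / agg["swxx"]).to_numpy()
    se = (1.0 / np.sqrt(agg["swxx"])).to_numpy()
    q = np.maximum((agg["swyy"] - agg["swxy"] ** 2 / agg["swxx"]).to_numpy(), 0.0)
    single = k == 1
    # Wald ratio for single-instrument groups (same closed form, exact)
    beta[single] = (first["beta_out"] / first["beta_exp"]).to_numpy()[single]
    se[single] = (first["se_out"] / first["beta_exp"].abs()).to_numpy()[single]
    if ivw_mode == "mre":
        multi = k >= 2
        infl = np.ones_like(k)
        infl[multi] = np.sqrt(np.maximum(1.0, q[multi] / (k[multi] - 1)))
        se = se * infl
    elif ivw_mode != "fe":
        raise ValueError(f"unknown IVW mode {ivw_mode!r}")
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    with np.errstate(invalid="ignore"):
        q_pval = stats.chi2.sf(q, k - 1)
    res = pd.DataFrame(
        {
            "method": np.where(single, "wald", "ivw"),
            "beta": beta,
            "se": se,
            "pval": pval,
            "n_iv": k.astype(int),
            "q_stat": np.where(single, np.nan, q),
            "q_pval": np.where(single, np.nan, q_pval),
        },
        index=agg.index,
    )
    # Egger closed form for groups with >= 3 instruments
    # orientation flips both members of a pair, so w*bx*by and w*bx^2 are
    # orientation-invariant; only the single-factor sums swx/swy change
    denom = agg["sw"] * agg["swxx"] - agg["swx"] ** 2
    eligible = k >= 3
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = ((agg["sw"] * agg["swxy"] - agg["swx"] * agg["swy"]) / denom).to_numpy()
        intercept = ((agg["swy"] - slope * agg["swx"]) / agg["sw"]).to_numpy()
        slope = np.where(eligible, slope, np.nan)
        intercept = np.where(eligible, intercept, np.nan)
        rss = (
            agg["swyy"].to_numpy()
            - 2 * intercept * agg["swy"].to_numpy()
            - 2 * slope * agg["swxy"].to_numpy()
            + intercept**2 * agg["sw"].to_numpy()
            + 2 * intercept * slope * agg["swx"].to_numpy()
            + slope**2 * agg["swxx"].to_numpy()
        )
        sigma2 = np.maximum(rss, 0.0) / np.maximum(k - 2, 1)
        infl_e = np.maximum(1.0, sigma2)
        se_slope = np.sqrt(agg["sw"].to_numpy() / denom.to_numpy() * infl_e)
        se_int = np.sqrt(agg["swxx"].to_numpy() / denom.to_numpy() * infl_e)
        p_int = 2.0 * stats.t.sf(np.abs(intercept) / se_int, np.maximum(k - 2, 1))
        p_slope = 2.0 * stats.t.sf(np.abs(slope) / se_slope, np.maximum(k - 2, 1))
    for col, vals in [
        ("egger_beta", slope),
        ("egger_se", se_slope),
        ("egger_pval", p_slope),
        ("egger_intercept", intercept),
        ("egger_intercept_se", se_int),
        ("egger_intercept_pval", p_int),
    ]:
        res[col] = np.where(eligible, vals, np.nan)
    return res.reset_index()
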