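"""Cross-cohort trait harmonization and fixed-effect meta-analysis.

Per-cohort GWAS summary statistics are combined by inverse-variance-weighted
(IVW) fixed-effect meta-analysis, with Cochran's Q heterogeneity, a genomic
control (GC) inflation diagnostic, and a median-based GC correction applied to
traits whose lambda exceeds a threshold (default 1.15).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "meta_fixed_ivw",
    "meta_all",
    "underflow_floor",
    "genomic_lambda",
    "gc_correct",
    "map_traits",
]

#: Median of the 1-df chi-square distribution, the GC normalizing constant.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class MetaResult:
    """Fixed-effect meta-analysis of one variant-trait across cohorts."""

    beta: float
    se: float
    pval: float
    n: float
    eaf: float
    k: int
    q_stat: float | None
    q_pval: float | None


def meta_fixed_ivw(
    betas: Sequence[float],
    ses: Sequence[float],
    eafs: Sequence[float] | None = None,
    ns: Sequence[float] | None = None,
) -> MetaResult:
    """Inverse-variance-weighted fixed-effect meta-analysis of one variant.

    ``beta_meta = sum(w_i b_i) / sum(w_i)`` with ``w_i = 1/se_i^2``,
    ``se_meta = 1/sqrt(sum(w_i))``, two-sided normal p, and Cochran's
    ``Q = sum(w_i (b_i - beta_meta)^2)`` on ``k - 1`` df.  With a single
    cohort the input is passed through and Q is undefined (``None``).

    Inputs must already be harmonized to a common effect allele.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("at least one cohort record is required")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all standard errors must be finite and positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    n = float(np.sum(ns)) if ns is not None else float("nan")
    if eafs is not None and ns is not None:
        eaf = float(np.sum(np.asarray(eafs) * np.asarray(ns)) / np.sum(ns))
    elif eafs is not None:
        eaf = float(np.mean(eafs))
    else:
        eaf = float("nan")
    if b.size >= 2:
        q = float(np.sum(w * (b - beta) ** 2))
        q_p = float(stats.chi2.sf(q, b.size - 1))
    else:
        q, q_p = None, None
    return MetaResult(beta=beta, se=se, pval=pval, n=n, eaf=eaf, k=int(b.size), q_stat=q, q_pval=q_p)


def _align_to_reference(ref: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Flip ``other`` records whose alleles are swapped relative to ``ref``.

    The first cohort's effect allele wins; strand flips are resolved via the
    complement map.  Palindromic (A/T, C/G) pairs cannot be oriented by
    allele letters — a strand flip and an allele swap look identical — so
    they are oriented by which side of 0.5 their frequency falls on, and
    dropped when either frequency is too close to 0.5 (0.42-0.58) to call.
    Records whose allele pair cannot be reconciled are dropped.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    merged = other.merge(
        ref[["variant_id", "effect_allele", "other_allele", "eaf"]].rename(
            columns={"effect_allele": "ref_ea", "other_allele": "ref_oa", "eaf": "ref_eaf"}
        ),
        on="variant_id",
        how="inner",
    )
    ea, oa = merged["effect_allele"], merged["other_allele"]
    cea = ea.map(comp)
    coa = oa.map(comp)
    pal = (cea == oa).fillna(False)
    same = (ea == merged["ref_ea"]) & (oa == merged["ref_oa"])
    swapped = (ea == merged["ref_oa"]) & (oa == merged["ref_ea"])
    strand = (cea == merged["ref_ea"]) & (coa == merged["ref_oa"])
    strand_swapped = (cea == merged["ref_oa"]) & (coa == merged["ref_ea"])
    ambiguous = pal & (
        merged["eaf"].between(0.42, 0.58) | merged["ref_eaf"].between(0.42, 0.58)
    )
    pal_flip = pal & ~ambiguous & (
        np.sign(merged["eaf"] - 0.5) != np.sign(merged["ref_eaf"] - 0.5)
    )
    flip = ((swapped | strand_swapped) & ~same & ~strand & ~pal) | pal_flip
    keep = (same | swapped | strand | strand_swapped) & ~ambiguous
    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, "eaf"] = 1.0 - merged.loc[flip, "eaf"]
    merged["effect_allele"] = merged["ref_ea"]
    merged["other_allele"] = merged["ref_oa"]
    return merged[keep].drop(columns=["ref_ea", "ref_oa", "ref_eaf"])


def meta_all(cohort_frames: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Vectorized fixed-effect meta-analysis over per-cohort GWAS frames.

    Each frame carries the standard GWAS columns plus a canonical ``trait``
    column.  Variant-traits present in a single cohort pass through with
    heterogeneity set to missing.  Returns one row per (trait, variant).
    """
    names = list(cohort_frames)
    if not names:
        raise ValueError("no cohorts provided")
    ref_alleles = (
        pd.concat(
            [
                df[["variant_id", "effect_allele", "other_allele", "eaf"]]
                for df in cohort_frames.values()
            ],
            ignore_index=True,
        )
        .drop_duplicates("variant_id", keep="first")
    )
    aligned = []
    for name in names:
        df = _align_to_reference(ref_alleles, cohort_frames[name])
        aligned.append(df.assign(_cohort=name))
    stacked = pd.concat(aligned, ignore_index=True)
    w = 1.0 / stacked["se"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["beta"], _wn=stacked["eaf"] * stacked["n"])
    g = stacked.groupby(["trait", "variant_id"], sort=False)
    agg = g.agg(
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
        _wn=("_wn", "sum"),
        n=("n", "sum"),
        k=("beta", "size"),
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        effect_allele=("effect_allele", "first"),
        other_allele=("other_allele", "first"),
    )
    agg["beta"] = agg["_wb"] / agg["_w"]
    agg["se"] = 1.0 / np.sqrt(agg["_w"])
    agg["eaf"] = agg["_wn"] / agg["n"]
    # Q = sum w_i b_i^2 - beta_meta^2 * sum w_i  (algebraic expansion)
    wbb = stacked.assign(_wbb=stacked["_w"] * stacked["beta"] ** 2).groupby(
        ["trait", "variant_id"], sort=False
    )["_wbb"].sum()
    agg["q_stat"] = np.maximum(wbb - agg["beta"] ** 2 * agg["_w"], 0.0)
    agg["q_pval"] = stats.chi2.sf(agg["q_stat"], agg["k"] - 1)
    agg.loc[agg["k"] < 2, ["q_stat", "q_pval"]] = np.nan
    agg["pval"] = underflow_floor(2.0 * stats.norm.sf(np.abs(agg["beta"] / agg["se"])))
    out = agg.reset_index().drop(columns=["_w", "_wb", "_wn"])
    return out


def underflow_floor(pval):
    """Replace p-values of exactly zero by the smallest positive normal float.

    Very strong associations underflow double precision; a literal zero breaks
    downstream -log10 transforms, so it is floored at ``sys.float_info.min``
    (2.2250738585072014e-308).  Scalars and arrays are both accepted.
    """
    p = np.asarray(pval, dtype=float)
    if np.any(p < 0):
        raise ValueError("p-values must be non-negative")
    out = np.where(p == 0.0, sys.float_info.min, p)
    return float(out) if np.isscalar(pval) or np.ndim(pval) == 0 else out


def genomic_lambda(pvals) -> float:
    """Genomic-control inflation factor of a set of association p-values.

    lambda = median(chi2_1 quantile of 1 - p) / median(chi2_1).  Values near 1
    indicate a calibrated null; lambda > 1 indicates inflation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("cannot compute lambda from an empty p-value set")
    if p.size < 100:
        warnings.warn("genomic_lambda is unstable below ~100 p-values", stacklevel=2)
    chisq = stats.chi2.isf(np.clip(p, 0.0, 1.0), 1)
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def gc_correct(records: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Apply genomic-control correction: chi-squares divided by lambda.

    Equivalently the SE is inflated by sqrt(lambda) and p recomputed.  The
    pipeline driver only calls this for traits with lambda above its
    threshold; lambda = 1 leaves records unchanged.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    out = records.copy()
    out["se"] = out["se"] * np.sqrt(lam)
    out["pval"] = underflow_floor(2.0 * stats.norm.sf(np.abs(out["beta"] / out["se"])))
    return out


def map_traits(
    mapping: pd.DataFrame, cohort_tables: Mapping[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Join cohort GWAS tables on canonical trait ids.

    ``mapping`` has columns (cohort, code, trait, provenance).  A cohort code
    mapping to two canonical ids is rejected.  Cohort-specific codes absent
    from the mapping are retained as single-cohort traits under their own
    code, mirroring the practice of analyzing unmapped biobank phenotypes on
    their own.
    """
    dup = mapping.groupby(["cohort", "code"])["trait"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"cohort codes mapping to multiple canonical traits: {bad}")
    out = {}
    for cohort, df in cohort_tables.items():
        m = mapping.loc[mapping["cohort"] == cohort, ["code", "trait"]]
        joined = df.merge(m, left_on="trait_code", right_on="code", how="left")
        joined["trait"] = joined["trait"].fillna(joined["trait_code"])
        out[cohort] = joined.drop(columns=["code"])
    return out
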