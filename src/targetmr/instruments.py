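"""Per-source instrument assembly and instrument-strength diagnostics.

Five instrument sources are modeled: two eQTL panels (a tissue-resolved
GTEx-style panel and a blood eQTLGen-style panel distributed as z-scores) and
three plasma pQTL panels (deCODE-, Fenland- and ARIC-style curated lists).
Strength is summarized by the proportion of variance explained (PVE) and the
first-stage F-statistic, with F < 10 flagging a weak instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SourceSpec",
    "zscore_to_beta_se",
    "pve",
    "f_statistic",
    "annotate_strength",
    "select_instruments",
    "PQTL_SOURCES",
    "EQTL_SOURCES",
]

PQTL_SOURCES = frozenset({"decode", "fenland", "aric"})
EQTL_SOURCES = frozenset({"gtex", "eqtlgen"})

#: F-statistic threshold below which an instrument is considered weak.
WEAK_F_THRESHOLD = 10.0


@dataclass
class SourceSpec:
    """Selection rules for one instrument source.

    mode
        ``"min_p"``: keep the single smallest-p variant per gene (blood eQTL
        convention); ``"threshold_topk"``: keep up to ``max_signals``
        conditional signals per gene (and tissue) passing ``sig_threshold``
        (tissue-panel convention); ``"curated"``: pass through an
        author-curated list after per-gene de-duplication by (chrom, pos).
    """

    name: str
    layer: str  # "eqtl" | "pqtl"
    mode: str  # "min_p" | "threshold_topk" | "curated"
    sig_threshold: float = 5e-8
    max_signals: int = 5

    def __post_init__(self):
        if self.layer not in ("eqtl", "pqtl"):
            raise ValueError(f"unknown molecular layer {self.layer!r}")
        if self.mode not in ("min_p", "threshold_topk", "curated"):
            raise ValueError(f"unknown selection mode {self.mode!r}")


def zscore_to_beta_se(z, p, n):
    """Recover (beta, se) from a z-score, allele frequency and sample size.

    beta = z / sqrt(2 p (1-p) (n + z^2)), se = 1 / sqrt(2 p (1-p) (n + z^2)),
    so that beta/se restores z exactly.  ``p`` is the effect-allele frequency.
    """
    z = np.asarray(z, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("allele frequency must be in (0, 1)")
    if np.any(n_arr <= 0):
        raise ValueError("sample size must be positive")
    denom = np.sqrt(2.0 * p_arr * (1.0 - p_arr) * (n_arr + z**2))
    beta = z / denom
    se = 1.0 / denom
    if np.ndim(z) == 0 and np.ndim(p) == 0 and np.ndim(n) == 0:
        return float(beta), float(se)
    return beta, se


def pve(beta, maf, se, n):
    """Proportion of exposure variance explained by a single variant.

    PVE = 2 b^2 q(1-q) / (2 b^2 q(1-q) + se^2 * 2 n q(1-q)), with q the minor
    allele frequency.  Symmetric in q vs 1-q and zero for a null effect.
    """
    beta = np.asarray(beta, dtype=float)
    maf_arr = np.asarray(maf, dtype=float)
    se_arr = np.asarray(se, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any((maf_arr <= 0) | (maf_arr >= 1)):
        raise ValueError("MAF must be in (0, 1)")
    if np.any(se_arr <= 0):
        raise ValueError("SE must be positive")
    if np.any(n_arr <= 1):
        raise ValueError("sample size must exceed 1")
    het = 2.0 * maf_arr * (1.0 - maf_arr)
    num = beta**2 * het
    out = num / (num + se_arr**2 * n_arr * het)
    if out.ndim == 0:
        return float(out)
    return out


def f_statistic(pve_value, n, k=1):
    """First-stage F-statistic of an instrument set from its PVE.

    F = PVE (n - 1 - k) / ((1 - PVE) k) for an instrument set of size ``k``
    in a first-stage sample of size ``n``.
    """
    q = np.asarray(pve_value, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    k_arr = np.asarray(k, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("PVE must be in [0, 1)")
    if np.any(k_arr < 1):
        raise ValueError("k must be at least 1")
    if np.any(n_arr <= k_arr + 1):
        raise ValueError("sample size must exceed k + 1")
    out = q * (n_arr - 1.0 - k_arr) / ((1.0 - q) * k_arr)
    if out.ndim == 0:
        return float(out)
    return out


def annotate_strength(instruments: pd.DataFrame) -> pd.DataFrame:
    """Add per-variant pve, f_stat and weak columns to an instrument table.

    Per-variant diagnostics use k = 1; MAF is folded from the effect-allele
    frequency as min(eaf, 1 - eaf).
    """
    out = instruments.copy()
    maf = np.minimum(out["eaf"], 1.0 - out["eaf"])
    out["pve"] = pve(out["beta"].to_numpy(), maf.to_numpy(), out["se"].to_numpy(), out["n"].to_numpy())
    out["f_stat"] = f_statistic(out["pve"].to_numpy(), out["n"].to_numpy(), 1)
    out["weak"] = out["f_stat"] < WEAK_F_THRESHOLD
    return out


def select_instruments(table: pd.DataFrame, spec: SourceSpec) -> pd.DataFrame:
    """Apply a source's instrument-selection rule to its association table.

    Duplicate (gene, variant) rows are collapsed keeping the smallest p.
    Argmin-p ties break by (chrom, pos) then variant id, so selection is
    deterministic.  All retained instruments for a gene are distinct variants.
    """
    df = table.copy()
    group_cols = ["gene", "tissue"] if "tissue" in df.columns and df["tissue"].notna().any() else ["gene"]
    df = (
        df.sort_values(["pval", "chrom", "pos", "variant_id"], kind="mergesort")
        .drop_duplicates(group_cols + ["variant_id"], keep="first")
    )
    if spec.mode == "min_p":
        df = df.drop_duplicates(group_cols, keep="first")
    elif spec.mode == "threshold_topk":
        df = df[df["pval"] < spec.sig_threshold]
        df = df.groupby(group_cols, sort=False).head(spec.max_signals)
    elif spec.mode == "curated":
        df = df.drop_duplicates(group_cols + ["chrom", "pos"], keep="first")
    return df.sort_values(group_cols + ["chrom", "pos", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )
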