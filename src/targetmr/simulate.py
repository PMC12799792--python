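"""Synthetic-world generator with known ground truth.

Every input the pipeline consumes is emulated here: per-cohort GWAS summary
statistics for a panel of quantitative traits, per-source QTL instrument
tables (two eQTL panels, one tissue-resolved; three pQTL panels), a drug
catalog whose approved target-indications partially coincide with the planted
causal gene-trait pairs, protein-interaction edge lists with clustered
true-positive neighborhoods, orthogonal-evidence catalogs enriched for causal
pairs, a GWAS-catalog-style association table, and the truth table itself.

The generative model, briefly: each gene-trait pair is causal with
probability ``frac_causal`` and carries a true per-unit-exposure effect drawn
N(0, effect_sd^2).  Instruments are mutually independent variants (no LD)
whose exposure effect sizes are drawn on the z scale with SEs consistent with
MAF and first-stage sample size, SE = 1/sqrt(2 MAF (1-MAF) n).  Outcome
effects are ``true_effect x exposure beta`` plus cohort heterogeneity and
sampling noise at the outcome SE; traits are oriented so a positive effect
means higher disease risk.  A configurable fraction of causal pairs has the
eQTL-layer sign flipped relative to the pQTL layer, to exercise the
concordance rules.  Genomic inflation multiplies null chi-squares by
``inflation_lambda``.  Alleles are drawn from {A,C,G,T} and a fraction of
outcome records is emitted with swapped or strand-complemented alleles to
exercise harmonization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionDataset
from .gwas_meta import underflow_floor
from .instruments import EQTL_SOURCES

__all__ = ["SimConfig", "World", "generate_world", "generate_region_panel", "inflated_null_pvalues"]

#: First-stage sample sizes per instrument source (realistic panel sizes).
SOURCE_SAMPLE_SIZES = {
    "gtex": 670,
    "eqtlgen": 31_684,
    "decode": 35_559,
    "fenland": 10_708,
    "aric": 7_213,
}

TISSUES = ("adipose", "liver", "lung")

_SYSTEMS = (
    "cardiovascular",
    "respiratory",
    "metabolic",
    "neurological",
    "immune",
    "renal",
    "hepatic",
    "dermatological",
    "musculoskeletal",
    "hematological",
    "endocrine",
    "psychiatric",
)

_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic world.

    Defaults define a desk-scale analogue of a multi-biobank target-discovery
    study: 50 traits x 500 genes across three cohorts, 2% of gene-trait pairs
    causal with effects of SD 0.35 per unit exposure, five instrument sources
    with realistic MAF/SE structure, and a drug catalog in which 60% of
    approved target-indications are drawn from the causal pairs.
    """

    n_traits: int = 50
    n_genes: int = 500
    n_cohorts: int = 3
    frac_causal: float = 0.02
    effect_sd: float = 0.35
    n_instruments_per_gene_per_source: tuple[int, int] = (1, 3)
    maf_range: tuple[float, float] = (0.05, 0.5)
    cohort_n_range: tuple[int, int] = (50_000, 200_000)
    inflation_lambda: float = 1.0
    het_sd: float = 0.002
    seed: int = 0
    frac_discordant_sources: float = 0.10
    drug_overlap: float = 0.6

    # instrument structure
    instrument_z_range: tuple[float, float] = (7.0, 25.0)
    weak_fraction: float = 0.05
    frac_palindromic: float = 0.05
    n_tissues_per_gene: tuple[int, int] = (1, 2)

    # allele presentation of emitted outcome records
    frac_allele_swap: float = 0.25
    frac_strand_flip: float = 0.10

    # cohort/trait structure
    frac_single_cohort_traits: float = 0.10

    # drug catalog
    n_approved_pairs: int = 120
    n_dev_pairs: int = 80
    frac_sibling_indication: float = 0.2
    moa_concordance: float = 0.85
    frac_moa_other: float = 0.10

    # orthogonal evidence
    evidence_rate_causal: float = 0.30
    evidence_rate_null: float = 0.005
    frac_sibling_term: float = 0.15

    # GWAS-catalog associations
    catalog_coverage: float = 0.60
    catalog_background: int = 200

    # PPI networks
    ppi_cluster_p: float = 0.40
    ppi_background_per_gene: int = 3

    def __post_init__(self):
        props = {
            "frac_causal": self.frac_causal,
            "frac_discordant_sources": self.frac_discordant_sources,
            "drug_overlap": self.drug_overlap,
            "frac_allele_swap": self.frac_allele_swap,
            "frac_strand_flip": self.frac_strand_flip,
            "frac_palindromic": self.frac_palindromic,
            "weak_fraction": self.weak_fraction,
            "evidence_rate_causal": self.evidence_rate_causal,
            "evidence_rate_null": self.evidence_rate_null,
            "catalog_coverage": self.catalog_coverage,
            "moa_concordance": self.moa_concordance,
            "ppi_cluster_p": self.ppi_cluster_p,
            "frac_single_cohort_traits": self.frac_single_cohort_traits,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.inflation_lambda < 1.0:
            raise ValueError("inflation_lambda must be >= 1")
        if not self.maf_range[0] < self.maf_range[1]:
            raise ValueError("maf_range must be a non-degenerate interval")
        if not self.cohort_n_range[0] < self.cohort_n_range[1]:
            raise ValueError("cohort_n_range must be a non-degenerate interval")
        lo, hi = self.n_instruments_per_gene_per_source
        if lo < 1 or hi < lo:
            raise ValueError("instrument count range must satisfy 1 <= lo <= hi")
        if self.frac_causal > 0 and self.frac_causal * self.n_genes * self.n_traits < 1:
            raise ValueError(
                "expected number of causal pairs below one; increase frac_causal or world size"
            )


@dataclass
class World:
    """One simulated study: all pipeline inputs plus the ground truth."""

    config: SimConfig
    genes: pd.DataFrame
    traits: pd.DataFrame
    sibling_terms: pd.DataFrame
    truth: pd.DataFrame
    instruments: Mapping[str, pd.DataFrame]
    gwas: Mapping[str, pd.DataFrame]
    trait_mapping: pd.DataFrame
    drug_catalog: pd.DataFrame
    ppi: Mapping[str, pd.DataFrame]
    evidence: Mapping[str, pd.DataFrame]
    catalog_associations: pd.DataFrame
    cohort_sizes: Mapping[str, int]
    cohort_traits: Mapping[str, list] = field(default_factory=dict)

    def causal_pairs(self) -> set[tuple[str, str]]:
        t = self.truth
        return set(map(tuple, t.loc[t["causal"], ["gene", "trait"]].to_numpy()))

    def true_effect(self, gene: str, trait: str) -> float:
        if not hasattr(self, "_effect_map"):
            self._effect_map = {
                (g, t): e for g, t, e in self.truth[["gene", "trait", "true_effect"]].itertuples(index=False)
            }
        return self._effect_map.get((gene, trait), 0.0)

    def outcome_n(self, trait: str) -> float:
        return float(sum(self.cohort_sizes[c] for c, ts in self.cohort_traits.items() if trait in ts))

    def region_pair(self, gene: str, trait: str, instrument_row, n_variants: int = 50):
        """Regional QTL/GWAS summary-statistic pair around one instrument.

        Regions are generated lazily with a seed derived from the world seed
        and the (gene, trait, variant) identity, sharing the causal variant
        exactly when the pair is truly causal; a non-causal pair yields a QTL
        peak over a null GWAS region.
        """
        variant_id = instrument_row["variant_id"]
        seed = zlib.crc32(f"{self.config.seed}|{gene}|{trait}|{variant_id}".encode()) & 0x7FFFFFFF
        te = self.true_effect(gene, trait)
        z_qtl = instrument_row["beta"] / instrument_row["se"]
        if te != 0.0:
            n_out = self.outcome_n(trait)
            maf = min(instrument_row["eaf"], 1 - instrument_row["eaf"])
            se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * max(n_out, 1.0))
            z_gwas = te * instrument_row["beta"] / se_out
        else:
            z_gwas = 0.0
        return generate_region_panel(
            gene=gene,
            shared_causal=te != 0.0,
            n_variants=n_variants,
            seed=seed,
            center_pos=int(instrument_row["pos"]),
            peak_z1=float(z_qtl),
            peak_z2=float(z_gwas),
            n1=float(instrument_row["n"]),
            n2=self.outcome_n(trait) or 1e5,
        )


def inflated_null_pvalues(n: int, inflation_lambda: float, seed: int) -> np.ndarray:
    """Null association p-values with genomic inflation.

    Chi-square statistics of null z-scores are multiplied by
    ``inflation_lambda`` before p-values are recomputed — the same mechanism
    the world generator applies to its null outcome records.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n) * np.sqrt(inflation_lambda)
    return 2.0 * stats.norm.sf(np.abs(z))


def _draw_alleles(rng: np.random.Generator, size: int, frac_palindromic: float):
    pal = rng.random(size) < frac_palindromic
    idx_np = rng.integers(0, len(_NONPAL_PAIRS), size)
    idx_p = rng.integers(0, len(_PAL_PAIRS), size)
    np_ea = np.array([p[0] for p in _NONPAL_PAIRS])
    np_oa = np.array([p[1] for p in _NONPAL_PAIRS])
    p_ea = np.array([p[0] for p in _PAL_PAIRS])
    p_oa = np.array([p[1] for p in _PAL_PAIRS])
    ea = np.where(pal, p_ea[idx_p], np_ea[idx_np])
    oa = np.where(pal, p_oa[idx_p], np_oa[idx_np])
    return ea, oa


def _make_genes(cfg: SimConfig) -> pd.DataFrame:
    idx = np.arange(cfg.n_genes)
    chrom = (idx % 22 + 1).astype(str)
    slot = idx // 22
    tss = 1_000_000 + slot * 600_000
    rng = np.random.default_rng(cfg.seed + 1)
    length = rng.integers(5_000, 100_000, cfg.n_genes)
    return pd.DataFrame(
        {
            "gene": [f"G{i:04d}" for i in idx],
            "chrom": chrom,
            "tss": tss,
            "tes": tss + length,
        }
    )


def _make_traits(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    idx = np.arange(cfg.n_traits)
    systems = [_SYSTEMS[i % len(_SYSTEMS)] for i in idx]
    traits = pd.DataFrame(
        {
            "trait": [f"T{i:03d}" for i in idx],
            "label": [f"{s} disorder {i:03d}" for i, s in zip(idx, systems)],
            "code": [f"EFO:{100000 + i}" for i in idx],
            "parents": [f"{s} disease" for s in systems],
        }
    )
    siblings = pd.DataFrame(
        {
            "trait": traits["trait"],
            "label": [f"{s} condition {i:03d}" for i, s in zip(idx, systems)],
            "code": [f"EFO:{200000 + i}" for i in idx],
            "parents": traits["parents"],
        }
    )
    return traits, siblings


def _make_truth(cfg: SimConfig, genes, traits, rng) -> pd.DataFrame:
    n_g, n_t = cfg.n_genes, cfg.n_traits
    causal = rng.random((n_g, n_t)) < cfg.frac_causal
    if cfg.frac_causal > 0 and not causal.any():
        causal[rng.integers(n_g), rng.integers(n_t)] = True
    effect = np.where(causal, rng.normal(0.0, cfg.effect_sd, (n_g, n_t)), 0.0)
    eqtl_flip = causal & (rng.random((n_g, n_t)) < cfg.frac_discordant_sources)
    gi, ti = np.nonzero(np.ones((n_g, n_t), dtype=bool))
    return pd.DataFrame(
        {
            "gene": genes["gene"].to_numpy()[gi],
            "trait": traits["trait"].to_numpy()[ti],
            "true_effect": effect[gi, ti],
            "causal": causal[gi, ti],
            "eqtl_sign": np.where(eqtl_flip[gi, ti], -1, 1),
        }
    )


def _make_instruments(cfg: SimConfig, genes: pd.DataFrame, rng) -> dict[str, pd.DataFrame]:
    lo, hi = cfg.n_instruments_per_gene_per_source
    counter = 0
    out: dict[str, pd.DataFrame] = {}
    for source, n_src in SOURCE_SAMPLE_SIZES.items():
        if source == "gtex":
            n_tis = rng.integers(cfg.n_tissues_per_gene[0], cfg.n_tissues_per_gene[1] + 1, cfg.n_genes)
            gene_idx = np.repeat(np.arange(cfg.n_genes), n_tis)
            tissue = np.concatenate(
                [rng.choice(TISSUES, size=k, replace=False) for k in n_tis]
            )
        else:
            gene_idx = np.arange(cfg.n_genes)
            tissue = np.array([None] * cfg.n_genes, dtype=object)
        k_per_unit = rng.integers(lo, hi + 1, gene_idx.size)
        g = np.repeat(gene_idx, k_per_unit)
        tis = np.repeat(tissue, k_per_unit)
        m = g.size
        tss = genes["tss"].to_numpy()[g]
        pos = tss + rng.integers(-500_000, 500_001, m)
        maf = rng.uniform(*cfg.maf_range, m)
        weak = rng.random(m) < cfg.weak_fraction
        z_mag = np.where(weak, rng.uniform(1.5, 3.0, m), rng.uniform(*cfg.instrument_z_range, m))
        z = z_mag * np.where(rng.random(m) < 0.5, -1.0, 1.0)
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_src)
        beta = z * se
        ea, oa = _draw_alleles(rng, m, cfg.frac_palindromic)
        eaf = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)
        df = pd.DataFrame(
            {
                "source": source,
                "gene": genes["gene"].to_numpy()[g],
                "tissue": tis,
                "variant_id": [f"rs{1_000_000 + counter + i}" for i in range(m)],
                "chrom": genes["chrom"].to_numpy()[g],
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": underflow_floor(2.0 * stats.norm.sf(np.abs(z))),
                "n": n_src,
            }
        )
        df["_gene_idx"] = g
        counter += m
        out[source] = df
    return out


def _make_gwas(cfg: SimConfig, master: pd.DataFrame, truth_effect: np.ndarray,
               eqtl_sign: np.ndarray, traits: pd.DataFrame, rng):
    """Per-cohort outcome GWAS over all instrumented variants and traits."""
    n_v = len(master)
    n_t = cfg.n_traits
    gi = master["_gene_idx"].to_numpy()
    is_eqtl = master["source"].isin(EQTL_SOURCES).to_numpy()
    te = truth_effect[gi, :]  # (n_v, n_t)
    sign = np.where(is_eqtl[:, None], eqtl_sign[gi, :], 1.0)
    by_true = te * sign * master["beta"].to_numpy()[:, None]
    maf = np.minimum(master["eaf"], 1.0 - master["eaf"]).to_numpy()

    # trait availability per cohort: a fraction of traits is cohort-0 only
    single = rng.random(n_t) < cfg.frac_single_cohort_traits
    cohort_names = [f"cohort{c}" for c in range(cfg.n_cohorts)]
    cohort_traits = {
        name: [t for j, t in enumerate(traits["trait"]) if c == 0 or not single[j]]
        for c, name in enumerate(cohort_names)
    }
    cohort_sizes = {
        name: int(rng.integers(*cfg.cohort_n_range)) for name in cohort_names
    }

    gwas: dict[str, pd.DataFrame] = {}
    mapping_rows = []
    provenances = np.array(["direct", "icd10-derived", "manual"])
    for c, name in enumerate(cohort_names):
        tmask = np.array([t in cohort_traits[name] for t in traits["trait"]])
        tsel = np.flatnonzero(tmask)
        n_tc = tsel.size
        n_c = cohort_sizes[name]
        se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_c)
        b = (
            by_true[:, tsel]
            + rng.normal(0.0, cfg.het_sd, (n_v, n_tc))
            + rng.standard_normal((n_v, n_tc)) * se_y[:, None]
        )
        if cfg.inflation_lambda > 1.0:
            null = by_true[:, tsel] == 0.0
            b = np.where(null, b * np.sqrt(cfg.inflation_lambda), b)
        pv = 2.0 * stats.norm.sf(np.abs(b) / se_y[:, None])

        codes = np.array([f"{name}:{traits['trait'].iloc[j]}" for j in tsel])
        flat = pd.DataFrame(
            {
                "variant_id": np.repeat(master["variant_id"].to_numpy(), n_tc),
                "chrom": np.repeat(master["chrom"].to_numpy(), n_tc),
                "pos": np.repeat(master["pos"].to_numpy(), n_tc),
                "effect_allele": np.repeat(master["effect_allele"].to_numpy(), n_tc),
                "other_allele": np.repeat(master["other_allele"].to_numpy(), n_tc),
                "eaf": np.repeat(master["eaf"].to_numpy(), n_tc),
                "beta": b.ravel(),
                "se": np.repeat(se_y, n_tc),
                "pval": underflow_floor(pv.ravel()),
                "n": n_c,
                "n_cases": np.nan,
                "trait_code": np.tile(codes, n_v),
            }
        )
        # allele presentation: swapped and/or strand-complemented records
        m = len(flat)
        swap = rng.random(m) < cfg.frac_allele_swap
        strand = rng.random(m) < cfg.frac_strand_flip
        ea = flat["effect_allele"].to_numpy().copy()
        oa = flat["other_allele"].to_numpy().copy()
        ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
        flat.loc[swap, "beta"] = -flat.loc[swap, "beta"]
        flat.loc[swap, "eaf"] = 1.0 - flat.loc[swap, "eaf"]
        comp = np.vectorize(_COMPLEMENT.get, otypes=[object])
        ea[strand] = comp(ea[strand])
        oa[strand] = comp(oa[strand])
        flat["effect_allele"] = ea
        flat["other_allele"] = oa
        gwas[name] = flat
        for j in tsel:
            mapping_rows.append(
                {
                    "cohort": name,
                    "code": f"{name}:{traits['trait'].iloc[j]}",
                    "trait": traits["trait"].iloc[j],
                    "provenance": provenances[rng.integers(0, 3)],
                }
            )
    return gwas, pd.DataFrame(mapping_rows), cohort_sizes, cohort_traits


def _term_fields(traits, siblings, j: int, use_sibling: bool) -> dict:
    src = siblings if use_sibling else traits
    return {
        "label": src["label"].iloc[j],
        "code": src["code"].iloc[j],
        "parents": src["parents"].iloc[j],
    }


def _make_drug_catalog(cfg, genes, traits, siblings, truth, rng) -> pd.DataFrame:
    causal = truth[truth["causal"]]
    causal_pairs = list(map(tuple, causal[["gene", "trait"]].to_numpy()))
    pq_effect = dict(
        zip(map(tuple, truth[["gene", "trait"]].to_numpy()), truth["true_effect"])
    )
    n_approved = min(cfg.n_approved_pairs, cfg.n_genes * cfg.n_traits // 2)
    n_from_causal = min(int(round(cfg.drug_overlap * n_approved)), len(causal_pairs))
    chosen = [causal_pairs[i] for i in rng.choice(len(causal_pairs), n_from_causal, replace=False)] if n_from_causal else []
    causal_set = set(causal_pairs)
    picked = set(chosen)
    while len(picked) < n_approved:
        g = genes["gene"].iloc[rng.integers(cfg.n_genes)]
        t = traits["trait"].iloc[rng.integers(cfg.n_traits)]
        if (g, t) not in causal_set and (g, t) not in picked:
            picked.add((g, t))
    approved = sorted(picked)
    rows = []
    drug_counter = 0
    trait_pos = {t: j for j, t in enumerate(traits["trait"])}
    for g, t in approved:
        j = trait_pos[t]
        te = pq_effect.get((g, t), 0.0)
        expected = "inhibitor" if te > 0 else "activator"
        if te == 0.0:
            moa = ["inhibitor", "activator", "other"][rng.integers(0, 3)]
        elif rng.random() < cfg.frac_moa_other:
            moa = "other"
        elif rng.random() < cfg.moa_concordance:
            moa = expected
        else:
            moa = "activator" if expected == "inhibitor" else "inhibitor"
        term = _term_fields(traits, siblings, j, rng.random() < cfg.frac_sibling_indication)
        for _ in range(int(rng.integers(1, 3))):
            rows.append(
                {
                    "drug_id": f"D{drug_counter:04d}",
                    "target_gene": g,
                    "max_phase": 4,
                    "indication_label": term["label"],
                    "indication_code": term["code"],
                    "indication_parent": term["parents"],
                    "moa": moa,
                }
            )
            drug_counter += 1
    for _ in range(cfg.n_dev_pairs):
        g = genes["gene"].iloc[rng.integers(cfg.n_genes)]
        j = int(rng.integers(cfg.n_traits))
        term = _term_fields(traits, siblings, j, rng.random() < cfg.frac_sibling_indication)
        rows.append(
            {
                "drug_id": f"D{drug_counter:04d}",
                "target_gene": g,
                "max_phase": int(rng.integers(1, 4)),
                "indication_label": term["label"],
                "indication_code": term["code"],
                "indication_parent": term["parents"],
                "moa": ["inhibitor", "activator", "other"][rng.integers(0, 3)],
            }
        )
        drug_counter += 1
    return pd.DataFrame(rows)


def _make_ppi(cfg, genes, truth, rng) -> dict[str, pd.DataFrame]:
    resources = {"stringdb": True, "hippie": True, "litbm": False}
    causal_by_trait = (
        truth[truth["causal"]].groupby("trait")["gene"].apply(list).to_dict()
    )
    cluster_edges = set()
    for gene_list in causal_by_trait.values():
        gs = sorted(gene_list)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                if rng.random() < cfg.ppi_cluster_p:
                    cluster_edges.add((gs[i], gs[j]))
    all_genes = genes["gene"].to_numpy()
    out = {}
    for resource, scored in resources.items():
        rows = []
        for a, b in sorted(cluster_edges):
            if rng.random() < 0.6:
                rows.append({"gene_a": a, "gene_b": b,
                             "score": rng.uniform(0.75, 1.0) if scored else np.nan})
        n_bg = cfg.ppi_background_per_gene * cfg.n_genes
        ia = rng.integers(0, cfg.n_genes, n_bg)
        ib = rng.integers(0, cfg.n_genes, n_bg)
        for a_i, b_i in zip(ia, ib):
            if a_i == b_i:
                continue
            a, b = sorted((all_genes[a_i], all_genes[b_i]))
            rows.append({"gene_a": a, "gene_b": b,
                         "score": rng.uniform(0.1, 0.85) if scored else np.nan})
        df = pd.DataFrame(rows).drop_duplicates(["gene_a", "gene_b"], keep="first")
        out[resource] = df.reset_index(drop=True)
    return out


def _make_evidence(cfg, traits, siblings, truth, rng) -> dict[str, pd.DataFrame]:
    trait_pos = {t: j for j, t in enumerate(traits["trait"])}
    out = {}
    for source in ("omim", "clinvar", "plof", "ko"):
        rate = np.where(truth["causal"], cfg.evidence_rate_causal, cfg.evidence_rate_null)
        take = rng.random(len(truth)) < rate
        rows = []
        for g, t in truth.loc[take, ["gene", "trait"]].itertuples(index=False):
            j = trait_pos[t]
            term = _term_fields(traits, siblings, j, rng.random() < cfg.frac_sibling_term)
            rows.append({"gene": g, "trait": t, **term, "source_group": source})
        out[source] = pd.DataFrame(rows, columns=["gene", "trait", "label", "code", "parents", "source_group"])
    return out


def _make_catalog(cfg, genes, traits, siblings, truth, rng) -> pd.DataFrame:
    trait_pos = {t: j for j, t in enumerate(traits["trait"])}
    gene_rows = genes.set_index("gene")
    rows = []
    causal = truth[truth["causal"]]
    for g, t in causal[["gene", "trait"]].itertuples(index=False):
        if rng.random() >= cfg.catalog_coverage:
            continue
        j = trait_pos[t]
        term = _term_fields(traits, siblings, j, rng.random() < cfg.frac_sibling_term)
        grow = gene_rows.loc[g]
        rows.append(
            {
                "chrom": grow["chrom"],
                "pos": int(rng.integers(grow["tss"], grow["tes"] + 1)),
                **term,
                "source_group": "gwas-catalog",
            }
        )
    for _ in range(cfg.catalog_background):
        grow = gene_rows.iloc[rng.integers(cfg.n_genes)]
        j = int(rng.integers(cfg.n_traits))
        term = _term_fields(traits, siblings, j, rng.random() < cfg.frac_sibling_term)
        rows.append(
            {
                "chrom": grow["chrom"],
                "pos": int(rng.integers(grow["tss"], grow["tes"] + 1)),
                **term,
                "source_group": "gwas-catalog",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "label", "code", "parents", "source_group"])


def generate_world(config: SimConfig) -> World:
    """Generate a complete synthetic study from one configuration.

    Deterministic: the same configuration (including seed) yields identical
    tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _make_genes(cfg)
    traits, siblings = _make_traits(cfg)
    truth = _make_truth(cfg, genes, traits, rng)
    effect_mat = truth["true_effect"].to_numpy().reshape(cfg.n_genes, cfg.n_traits)
    sign_mat = truth["eqtl_sign"].to_numpy().reshape(cfg.n_genes, cfg.n_traits).astype(float)
    instruments = _make_instruments(cfg, genes, rng)
    master = pd.concat(instruments.values(), ignore_index=True)
    gwas, mapping, cohort_sizes, cohort_traits = _make_gwas(
        cfg, master, effect_mat, sign_mat, traits, rng
    )
    drug_catalog = _make_drug_catalog(cfg, genes, traits, siblings, truth, rng)
    ppi = _make_ppi(cfg, genes, truth, rng)
    evidence = _make_evidence(cfg, traits, siblings, truth, rng)
    catalog = _make_catalog(cfg, genes, traits, siblings, truth, rng)
    instruments = {k: v.drop(columns=["_gene_idx"]) for k, v in instruments.items()}
    return World(
        config=cfg,
        genes=genes,
        traits=traits,
        sibling_terms=siblings,
        truth=truth,
        instruments=instruments,
        gwas=gwas,
        trait_mapping=mapping,
        drug_catalog=drug_catalog,
        ppi=ppi,
        evidence=evidence,
        catalog_associations=catalog,
        cohort_sizes=cohort_sizes,
        cohort_traits=cohort_traits,
    )


def generate_region_panel(
    gene: str = "G0000",
    shared_causal: bool = True,
    n_variants: int = 100,
    seed: int = 0,
    center_pos: int = 1_000_000,
    peak_z1: float = 10.0,
    peak_z2: float = 8.0,
    n1: float = 10_000,
    n2: float = 100_000,
    window: int = 250_000,
) -> tuple[RegionDataset, RegionDataset]:
    """Two aligned regional datasets for colocalization.

    When ``shared_causal``, both traits' association peaks sit on the same
    (central) variant with expected z-scores ``peak_z1`` and ``peak_z2``;
    otherwise the second trait's peak (if ``peak_z2 != 0``) sits on a distinct
    variant a quarter of the window away.  All other variants are null.  Both
    datasets are quantitative with sdY = 1.
    """
    if n_variants < 2:
        raise ValueError("a region panel needs at least two variants")
    rng = np.random.default_rng(seed)
    offsets = np.linspace(-window, window, n_variants).astype(int)
    pos = center_pos + offsets
    maf = rng.uniform(0.05, 0.5, n_variants)
    ids = [f"pv{i:04d}" for i in range(n_variants)]
    idx1 = n_variants // 2
    idx2 = idx1 if shared_causal else n_variants // 4
    frames = []
    for n_samp, z_peak, idx in ((n1, peak_z1, idx1), (n2, peak_z2, idx2)):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_samp)
        beta = rng.standard_normal(n_variants) * se
        if z_peak != 0.0:
            beta[idx] = z_peak * se[idx] + rng.standard_normal() * se[idx]
        frames.append(pd.DataFrame({"variant_id": ids, "pos": pos, "maf": maf, "beta": beta, "se": se}))
    d1 = RegionDataset(df=frames[0], trait_type="quant", n=float(n1), sdY=1.0)
    d2 = RegionDataset(df=frames[1], trait_type="quant", n=float(n2), sdY=1.0)
    return d1, d2
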