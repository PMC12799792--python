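"""End-to-end driver: synthetic world to ranked gene-trait pairs.

Stage order mirrors a genetics-driven target-discovery study:

1. map cohort trait codes to canonical traits and meta-analyze cohorts
   (fixed-effect IVW) with genomic-control handling;
2. assemble per-source instruments and strength diagnostics;
3. run two-sample MR per gene-trait-source(-tissue);
4. apply the multi-source concordance selection rules at the Bonferroni
   threshold;
5. colocalize selected signals, score novelty against an association
   catalog, map orthogonal evidence, and derive PPI neighborhood features;
6. map selected pairs onto the drug catalog (rediscovery / repurposing /
   safety calls, MoA concordance);
7. build the 10:1 positive/negative benchmark of approved target-indications
   and train the boosted-tree ranker; score all selected pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import benchmark as bench_mod
from . import coloc as coloc_mod
from . import drug_annot, gwas_meta, ppi as ppi_mod, ranker as ranker_mod
from .instruments import PQTL_SOURCES, SourceSpec, annotate_strength, select_instruments
from .mr import bonferroni_threshold, harmonize, mr_all
from .phenomap import GeneRegion, TermIndex, novelty_score
from .selection import decide_all, summarize_selection
from .simulate import SimConfig, World, generate_world

__all__ = ["PipelineResult", "run_pipeline", "SOURCE_SPECS"]

LAMBDA_THRESHOLD = 1.15

SOURCE_SPECS = {
    "gtex": SourceSpec("gtex", "eqtl", "threshold_topk", sig_threshold=5e-8, max_signals=5),
    "eqtlgen": SourceSpec("eqtlgen", "eqtl", "min_p"),
    "decode": SourceSpec("decode", "pqtl", "curated"),
    "fenland": SourceSpec("fenland", "pqtl", "curated"),
    "aric": SourceSpec("aric", "pqtl", "curated"),
}

_EVIDENCE_GROUP = {"omim": "omim", "clinvar": "clinvar", "plof": "plof", "ko": "ko-models"}


@dataclass
class PipelineResult:
    world: World
    meta: pd.DataFrame
    lambdas: Mapping[str, float]
    instruments_qc: pd.DataFrame
    mr_results: pd.DataFrame
    n_tests: int
    threshold: float
    decisions: pd.DataFrame
    selected: pd.DataFrame
    summary: dict
    term_index: TermIndex | None = None
    coloc_results: pd.DataFrame | None = None
    novelty: pd.DataFrame | None = None
    target_indications: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None
    moa: dict | None = None
    network: object = None
    benchmark: pd.DataFrame | None = None
    benchmark_features: object = None
    model_report: dict | None = None
    rankings: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _build_term_index(world: World) -> TermIndex:
    frames = [
        world.traits.assign(source_group="genetic-phenotypes")[
            ["label", "code", "parents", "source_group"]
        ],
        world.drug_catalog.rename(
            columns={"indication_label": "label", "indication_code": "code",
                     "indication_parent": "parents"}
        ).assign(source_group="drug-indications")[["label", "code", "parents", "source_group"]],
        world.catalog_associations[["label", "code", "parents", "source_group"]],
    ]
    for src, df in world.evidence.items():
        if len(df):
            frames.append(
                df.assign(source_group=_EVIDENCE_GROUP[src])[
                    ["label", "code", "parents", "source_group"]
                ]
            )
    terms = pd.concat(frames, ignore_index=True).drop_duplicates(["label", "source_group"])
    return TermIndex(terms=terms.reset_index(drop=True))


class _FeatureContext:
    """Per-pair feature lookups wired to the pipeline's stage outputs."""

    def __init__(self, result: PipelineResult, coloc_variants: int = 50):
        self.res = result
        self.world = result.world
        self.coloc_variants = coloc_variants
        self._coloc_cache: dict[tuple[str, str], dict] = {}
        mr = result.mr_results
        self._mr_by_pair = dict(tuple(mr.groupby(["gene", "trait"], sort=False).__iter__()))
        self._inst_by_source_gene = {
            (row.source, row.gene): None for row in result.instruments_qc.itertuples()
        }
        self._inst_groups = dict(
            tuple(result.instruments_qc.groupby(["source", "gene"], sort=False).__iter__())
        )
        self._selected_pairs = set(
            map(tuple, result.selected[["gene", "trait"]].to_numpy())
        ) if len(result.selected) else set()
        self._gene_regions = {
            row.gene: GeneRegion(row.gene, row.chrom, int(row.tss), int(row.tes))
            for row in self.world.genes.itertuples()
        }
        self._trait_terms = {
            row.trait: {"label": row.label, "code": row.code, "parents": row.parents,
                        "source_group": "genetic-phenotypes"}
            for row in self.world.traits.itertuples()
        }
        ti = result.target_indications
        self._drug_by_gene = dict(tuple(ti.groupby("target_gene", sort=False).__iter__())) if ti is not None else {}
        self._evidence_by_gene = {
            src: dict(tuple(df.groupby("gene", sort=False).__iter__())) if len(df) else {}
            for src, df in self.world.evidence.items()
        }
        mapped = bench_mod.map_indications_to_traits(
            ti[ti["max_phase"] == 4], self.world.traits
        ) if ti is not None and len(ti) else pd.DataFrame(columns=["target_gene", "trait"])
        self._approved_traits_by_gene = (
            mapped.groupby("target_gene")["trait"].apply(set).to_dict() if len(mapped) else {}
        )

    # -- helpers -----------------------------------------------------------
    def governing_source(self, gene: str, trait: str):
        """Representative (source, tissue) for a pair: its min-p MR result."""
        grp = self._mr_by_pair.get((gene, trait))
        if grp is None or grp.empty:
            return None
        row = grp.sort_values(["pval", "source"], kind="mergesort").iloc[0]
        return row

    def coloc_features(self, gene: str, trait: str) -> dict:
        key = (gene, trait)
        if key in self._coloc_cache:
            return self._coloc_cache[key]
        rep = self.governing_source(gene, trait)
        out = {"coloc_any_strong": None, "coloc_all_strong": None, "coloc_max_pph4": None}
        if rep is not None:
            inst = self._inst_groups.get((rep["source"], gene))
            if inst is not None and len(inst):
                tissue = rep.get("tissue")
                if "tissue" in inst.columns and pd.notna(tissue):
                    sub = inst[inst["tissue"] == tissue]
                    inst = sub if len(sub) else inst
                results = []
                for _, irow in inst.iterrows():
                    d1, d2 = self.world.region_pair(gene, trait, irow, n_variants=self.coloc_variants)
                    results.append(coloc_mod.coloc_posteriors(d1, d2))
                flags = coloc_mod.coloc_flags(results)
                out = {
                    "coloc_any_strong": flags["any_strong"],
                    "coloc_all_strong": flags["all_strong"],
                    "coloc_max_pph4": max(r["pp_h4"] for r in results),
                }
        self._coloc_cache[key] = out
        return out

    def approved_for_trait(self, gene: str, trait: str) -> bool:
        return trait in self._approved_traits_by_gene.get(gene, ())

    def evidence_features(self, gene: str, trait: str) -> dict:
        term = self._trait_terms[trait]
        idx = self.res.term_index
        out = {}
        for src in ("omim", "clinvar", "plof", "ko"):
            rows = self._evidence_by_gene.get(src, {}).get(gene)
            exact = parent = distance = False
            if rows is not None:
                group = _EVIDENCE_GROUP[src]
                neigh = idx.neighbors(term["label"], group) if idx is not None else frozenset()
                for r in rows.itertuples():
                    exact = exact or (r.code == term["code"])
                    parent = parent or (r.parents == term["parents"])
                    distance = distance or (r.label in neigh)
            out[f"ev_{src}_exact"] = exact
            out[f"ev_{src}_parent"] = parent
            out[f"ev_{src}_distance"] = distance
        return out

    def novelty_features(self, gene: str, trait: str) -> dict:
        region = self._gene_regions[gene]
        term = self._trait_terms[trait]
        catalog = self.world.catalog_associations
        return {
            "novelty_self": novelty_score(region, term, catalog, "exact"),
            "novelty_parent": novelty_score(region, term, catalog, "parent"),
            "novelty_distance": novelty_score(
                region, term, catalog, "distance", index=self.res.term_index
            ),
        }

    def feature_fn(self, gene: str, trait: str) -> dict:
        feats: dict = {}
        grp = self._mr_by_pair.get((gene, trait))
        if grp is not None and len(grp):
            rep = grp.sort_values(["pval", "source"], kind="mergesort").iloc[0]
            sig = grp[grp["pval"] <= self.res.threshold]
            feats.update(
                mr_min_mlog10p=-np.log10(max(rep["pval"], 5e-324)),
                mr_n_sig_sources=float(len(sig)),
                mr_layer_pqtl=float(any(s in PQTL_SOURCES for s in sig["source"])) if len(sig) else 0.0,
                mr_abs_beta=abs(rep["beta"]),
                mr_q_pval=rep["q_pval"],
                mr_egger_intercept_p=rep.get("egger_intercept_pval"),
            )
            inst = self._inst_groups.get((rep["source"], gene))
            if inst is not None and len(inst):
                feats.update(
                    inst_max_f=float(inst["f_stat"].max()),
                    inst_total_pve=float(inst["pve"].sum()),
                    inst_n=float(len(inst)),
                )
            feats.update({k: (None if v is None else float(v)) for k, v in self.coloc_features(gene, trait).items()})
        feats.update({k: float(v) for k, v in self.evidence_features(gene, trait).items()})
        feats.update({k: float(v) for k, v in self.novelty_features(gene, trait).items()})
        nb = ppi_mod.neighborhood_features(
            gene, trait, self.res.network, self._selected_pairs, self.approved_for_trait
        )
        feats.update(
            ppi_degree=float(nb["degree"]),
            ppi_n_neighbors_sig_same_trait=float(nb["n_neighbors_sig_same_trait"]),
            ppi_any_neighbor_approved_same_trait=float(nb["any_neighbor_approved_same_trait"]),
            ppi_res_stringdb=float("stringdb" in nb["resources"]),
            ppi_res_hippie=float("hippie" in nb["resources"]),
            ppi_res_litbm=float("litbm" in nb["resources"]),
        )
        entries = self._drug_by_gene.get(gene)
        feats.update(
            drug_is_target_any_phase=float(entries is not None),
            drug_max_phase=float(entries["max_phase"].max()) if entries is not None else 0.0,
        )
        return feats


def run_pipeline(
    config: SimConfig | None = None,
    world: World | None = None,
    alpha: float = 0.05,
    lambda_threshold: float = LAMBDA_THRESHOLD,
    ivw_mode: str = "fe",
    exclude_traits: tuple[str, ...] = (),
    run_model: bool = True,
    run_enrichment: bool = True,
    coloc_variants: int = 50,
) -> PipelineResult:
    """Run the full pipeline on a simulated world.

    Either a :class:`SimConfig` (a world is generated) or a prebuilt
    :class:`World` must be given.  ``exclude_traits`` removes traits from the
    meta-analysis outright (the escape hatch for pathologically inflated
    phenotypes).  Returns a :class:`PipelineResult` holding every stage
    output.
    """
    if world is None:
        if config is None:
            raise ValueError("provide a SimConfig or a World")
        world = generate_world(config)
    cfg = world.config

    # 1. trait harmonization + meta-analysis -------------------------------
    mapped = gwas_meta.map_traits(world.trait_mapping, world.gwas)
    if exclude_traits:
        mapped = {c: df[~df["trait"].isin(exclude_traits)] for c, df in mapped.items()}
    meta = gwas_meta.meta_all(mapped)

    # 2. genomic-control diagnostics per trait -----------------------------
    lambdas = {}
    corrected = []
    for trait, grp in meta.groupby("trait", sort=False):
        lam = gwas_meta.genomic_lambda(grp["pval"].to_numpy())
        lambdas[trait] = lam
        corrected.append(gwas_meta.gc_correct(grp, lam) if lam > lambda_threshold else grp)
    meta = pd.concat(corrected, ignore_index=True)

    # 3. instruments -------------------------------------------------------
    qc_frames = []
    for source, spec in SOURCE_SPECS.items():
        table = world.instruments.get(source)
        if table is None or table.empty:
            continue
        sel = select_instruments(table, spec)
        qc_frames.append(annotate_strength(sel))
    instruments_qc = pd.concat(qc_frames, ignore_index=True)

    # 4. two-sample MR per source ------------------------------------------
    harmonized_frames = []
    for source, grp in instruments_qc.groupby("source", sort=False):
        h = harmonize(grp, meta, keep_outcome_cols=("trait",))
        if len(h):
            harmonized_frames.append(h)
    harmonized = pd.concat(harmonized_frames, ignore_index=True)
    mr_results = mr_all(harmonized, group_cols=["gene", "trait", "source", "tissue"], ivw_mode=ivw_mode)
    mr_results["pval"] = gwas_meta.underflow_floor(mr_results["pval"].to_numpy())

    n_tests = int(mr_results[["gene", "trait"]].drop_duplicates().shape[0])
    threshold = bonferroni_threshold(alpha, n_tests)

    # 5. concordance selection ---------------------------------------------
    decisions = decide_all(mr_results, threshold)
    selected = decisions[decisions["verdict"] == "accepted"].reset_index(drop=True)
    summary = summarize_selection(decisions, n_tested=n_tests)

    result = PipelineResult(
        world=world,
        meta=meta,
        lambdas=lambdas,
        instruments_qc=instruments_qc,
        mr_results=mr_results,
        n_tests=n_tests,
        threshold=threshold,
        decisions=decisions,
        selected=selected,
        summary=summary,
    )
    result.term_index = _build_term_index(world)
    result.target_indications = drug_annot.dedupe_target_indications(world.drug_catalog)
    result.network = ppi_mod.build_network(world.ppi)

    ctx = _FeatureContext(result, coloc_variants=coloc_variants)
    result.extras["feature_context"] = ctx

    # 6. coloc + novelty for the selected set ------------------------------
    coloc_rows, novelty_rows = [], []
    for gene, trait in selected[["gene", "trait"]].itertuples(index=False):
        cfeat = ctx.coloc_features(gene, trait)
        coloc_rows.append({"gene": gene, "trait": trait, **cfeat})
        novelty_rows.append({"gene": gene, "trait": trait, **ctx.novelty_features(gene, trait)})
    result.coloc_results = pd.DataFrame(coloc_rows)
    result.novelty = pd.DataFrame(novelty_rows)

    # 7. drug-catalog calls ------------------------------------------------
    if len(selected):
        result.calls = drug_annot.classify_all(
            selected, result.target_indications, world.traits, result.term_index
        )
        redis = result.calls[
            (result.calls["call"] == "rediscovery") & result.calls["moa_concordant"].notna()
        ]
        result.moa = drug_annot.moa_concordance(result.calls) if len(redis) else None
    else:
        result.calls = pd.DataFrame(
            columns=["gene", "trait", "call", "matched_indication", "scheme", "moa_concordant"]
        )

    # 8. matched non-selected controls + evidence enrichment ---------------
    if run_enrichment and len(selected):
        controls = bench_mod.matched_nonselected(selected, mr_results, seed=cfg.seed + 11)
        pairs = pd.concat(
            [
                selected[["gene", "trait"]].assign(label=1),
                controls[["gene", "trait"]].assign(label=0),
            ],
            ignore_index=True,
        )
        ev = pd.DataFrame(
            [ctx.evidence_features(g, t) for g, t in pairs[["gene", "trait"]].itertuples(index=False)]
        )
        any_scheme = pd.DataFrame(
            {
                src: ev[[f"ev_{src}_exact", f"ev_{src}_parent", f"ev_{src}_distance"]].any(axis=1).astype(float)
                for src in ("omim", "clinvar", "plof", "ko")
            }
        )
        result.enrichment = bench_mod.enrichment_or(
            pairs["label"], any_scheme, continuity_correction=True
        )
        result.extras["matched_controls"] = controls

    # 9. benchmark + ranking model -----------------------------------------
    if run_model and len(decisions):
        sig_genes = sorted(decisions["gene"].unique())
        benchmark = bench_mod.build_benchmark(
            result.target_indications, world.traits, sig_genes, seed=cfg.seed + 17
        )
        result.benchmark = benchmark
        feats = ranker_mod.engineer_features(benchmark, ctx.feature_fn)
        result.benchmark_features = feats
        labels = (benchmark["label"] == "positive").astype(int).to_numpy()
        report = ranker_mod.train(feats.X, labels, seed=cfg.seed + 23)
        result.model_report = report
        if len(selected):
            sel_feats = ranker_mod.engineer_features(
                selected[["gene", "trait"]].reset_index(drop=True), ctx.feature_fn
            )
            result.rankings = ranker_mod.rank_all(
                report["model"], sel_feats, manifest=report["feature_manifest"]
            )
    return result
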