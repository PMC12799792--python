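"""Tabular I/O for the pipeline's TSV dialect.

Every table the pipeline reads or writes is plain TSV with a header row and
``NA`` for missing values, so intermediate results can be inspected with
standard command-line tools.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

#: Column order for GWAS summary-statistic tables (one row per variant).
GWAS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
]

#: Column order for QTL instrument tables.
INSTRUMENT_COLUMNS = [
    "source",
    "gene",
    "tissue",
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


def read_table(path: str) -> pd.DataFrame:
    """Read one of the pipeline's TSV tables."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a DataFrame in the pipeline's TSV dialect."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_world(world, outdir: str) -> None:
    """Emit a simulated world as the standard file layout.

    Files written: ``gwas.<cohort>.<trait>.tsv``, ``instruments.<source>.tsv``,
    ``drug_catalog.tsv``, ``ppi.<resource>.tsv``, ``evidence.<source>.tsv``,
    ``traits.tsv``, ``trait_mapping.tsv``, ``catalog_associations.tsv``,
    ``genes.tsv`` and ``truth.tsv``.
    """
    os.makedirs(outdir, exist_ok=True)
    for cohort, df in world.gwas.items():
        for code, sub in df.groupby("trait_code"):
            write_table(
                sub[GWAS_COLUMNS],
                os.path.join(outdir, f"gwas.{cohort}.{code}.tsv"),
            )
    for source, df in world.instruments.items():
        write_table(df[INSTRUMENT_COLUMNS], os.path.join(outdir, f"instruments.{source}.tsv"))
    for resource, df in world.ppi.items():
        write_table(df, os.path.join(outdir, f"ppi.{resource}.tsv"))
    for source, df in world.evidence.items():
        write_table(df, os.path.join(outdir, f"evidence.{source}.tsv"))
    write_table(world.drug_catalog, os.path.join(outdir, "drug_catalog.tsv"))
    write_table(world.traits, os.path.join(outdir, "traits.tsv"))
    write_table(world.trait_mapping, os.path.join(outdir, "trait_mapping.tsv"))
    write_table(world.catalog_associations, os.path.join(outdir, "catalog_associations.tsv"))
    write_table(world.genes, os.path.join(outdir, "genes.tsv"))
    write_table(world.truth, os.path.join(outdir, "truth.tsv"))


def read_gwas_dir(indir: str) -> Mapping[str, pd.DataFrame]:
    """Read ``gwas.<cohort>.<trait>.tsv`` files back into per-cohort frames."""
    per_cohort: dict[str, list[pd.DataFrame]] = {}
    for name in sorted(os.listdir(indir)):
        if not (name.startswith("gwas.") and name.endswith(".tsv")):
            continue
        _, cohort, code = name[:-4].split(".", 2)
        df = read_table(os.path.join(indir, name))
        df["trait_code"] = code
        per_cohort.setdefault(cohort, []).append(df)
    return {c: pd.concat(frames, ignore_index=True) for c, frames in per_cohort.items()}
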