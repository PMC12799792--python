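"""Semantic mapping of trait terms and GWAS-catalog-style novelty scoring.

Trait vocabularies from different resources (clinical ontologies, drug
indications, association catalogs, knockout phenotypes, …) rarely share
identifiers.  Three matching schemes are supported:

``exact``
    same ontology code;
``parent``
    overlapping parent-term sets (shared disease-system ancestor);
``distance``
    the candidate term lies in the query's top-3% cosine neighborhood of the
    candidate's source group, computed on fixed 200-dimensional embeddings.

The embedding encoder is pluggable: any deterministic callable mapping a
label to 200 floats.  The shipped :class:`NgramHashEncoder` hashes character
n-grams into 200 bins and L2-normalizes — enough to make lexically related
labels ("heart failure" / "cardiac failure") closer than unrelated ones,
without any model weights.

Novelty scoring asks whether a catalog already contains an association in the
gene's region (TSS − 250 kb to TES + 250 kb) for a matching trait: score 1
for a match (known), 0 for none (novel).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NgramHashEncoder",
    "encode",
    "TermIndex",
    "top_fraction_neighbors",
    "match",
    "GeneRegion",
    "novelty_score",
    "SOURCE_GROUPS",
]

SOURCE_GROUPS = (
    "clinvar",
    "drug-indications",
    "gwas-catalog",
    "ko-models",
    "genetic-phenotypes",
    "omim",
    "plof",
)

EMBED_DIM = 200
NEIGHBOR_FRACTION = 0.03
REGION_FLANK = 250_000


class NgramHashEncoder:
    """Deterministic toy text encoder: hashed character n-grams, L2-normalized.

    Uses CRC32 so vectors are stable across processes and platforms (Python's
    built-in ``hash`` is salted per process).
    """

    def __init__(self, dim: int = EMBED_DIM, n: int = 3):
        self.dim = dim
        self.n = n

    def encode(self, label: str) -> np.ndarray:
        if not label:
            raise ValueError("cannot encode an empty label")
        text = f"#{label.strip().lower()}#"
        vec = np.zeros(self.dim)
        for i in range(max(1, len(text) - self.n + 1)):
            gram = text[i : i + self.n]
            vec[zlib.crc32(gram.encode()) % self.dim] += 1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def encode(label: str, encoder=None) -> np.ndarray:
    """Encode a trait label into a 200-dimensional vector."""
    encoder = encoder or NgramHashEncoder()
    vec = np.asarray(encoder.encode(label), dtype=float)
    if vec.shape != (EMBED_DIM,):
        raise ValueError(f"encoder must return {EMBED_DIM} floats, got {vec.shape}")
    return vec


@dataclass
class TermIndex:
    """Vector index over trait terms grouped by source vocabulary.

    ``terms`` needs columns (label, source_group) and optionally
    (code, parents).  Vectors are computed once at construction and
    L2-normalized, so cosine similarity is a dot product.
    """

    terms: pd.DataFrame
    encoder: object = field(default_factory=NgramHashEncoder)

    def __post_init__(self):
        labels = self.terms["label"].tolist()
        mat = np.stack([encode(l, self.encoder) for l in labels]) if labels else np.zeros((0, EMBED_DIM))
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._matrix = mat / norms
        self._groups = {
            g: np.flatnonzero((self.terms["source_group"] == g).to_numpy())
            for g in self.terms["source_group"].unique()
        }
        self._cache: dict[tuple[str, str], frozenset] = {}

    def neighbors(self, query_label: str, group: str, fraction: float = NEIGHBOR_FRACTION) -> frozenset:
        """Top-``fraction`` most cosine-similar labels of ``group``.

        The cut keeps ``ceil(fraction * |group|)`` labels (never zero for a
        non-empty group); ties at the cut break lexicographically by label.
        """
        key = (query_label, group)
        if key in self._cache:
            return self._cache[key]
        idx = self._groups.get(group)
        if idx is None or idx.size == 0:
            return frozenset()
        q = encode(query_label, self.encoder)
        qn = np.linalg.norm(q)
        if qn > 0:
            q = q / qn
        sims = self._matrix[idx] @ q
        labels = self.terms["label"].to_numpy()[idx]
        k = math.ceil(fraction * idx.size)
        order = sorted(range(idx.size), key=lambda i: (-sims[i], labels[i]))
        result = frozenset(labels[i] for i in order[:k])
        self._cache[key] = result
        return result


def top_fraction_neighbors(
    query_label: str,
    index: TermIndex,
    fraction: float = NEIGHBOR_FRACTION,
) -> dict[str, frozenset]:
    """Per-source-group top-``fraction`` neighbor sets of a query term."""
    return {g: index.neighbors(query_label, g, fraction) for g in index._groups}


def _parents_of(term) -> set:
    parents = term.get("parents") if isinstance(term, dict) else term["parents"]
    if parents is None or (isinstance(parents, float) and np.isnan(parents)):
        return set()
    if isinstance(parents, str):
        return {p for p in parents.split(";") if p}
    return set(parents)


def match(term_a, term_b, scheme: str, index: TermIndex | None = None) -> bool:
    """Do two trait terms match under a scheme?

    Terms are mappings with keys label / code / parents / source_group.
    ``exact`` compares ontology codes (False, not an error, when either code
    is missing).  ``parent`` intersects parent-term sets.  ``distance`` asks
    whether ``term_b`` lies in ``term_a``'s top-3% neighborhood of
    ``term_b``'s source group — a relation that is not symmetric in general.
    """
    get = lambda t, k: t.get(k) if isinstance(t, dict) else t[k]
    if scheme == "exact":
        ca, cb = get(term_a, "code"), get(term_b, "code")
        if not ca or not cb or (isinstance(ca, float) and np.isnan(ca)) or (
            isinstance(cb, float) and np.isnan(cb)
        ):
            return False
        return ca == cb
    if scheme == "parent":
        return bool(_parents_of(term_a) & _parents_of(term_b))
    if scheme == "distance":
        if index is None:
            raise ValueError("distance matching needs a TermIndex")
        group = get(term_b, "source_group")
        return get(term_b, "label") in index.neighbors(get(term_a, "label"), group)
    raise ValueError(f"unknown matching scheme {scheme!r}")


@dataclass
class GeneRegion:
    """A gene's novelty-search window: TSS − 250 kb to TES + 250 kb."""

    gene: str
    chrom: str
    tss: int
    tes: int
    flank: int = REGION_FLANK

    def __post_init__(self):
        if self.tss > self.tes:
            raise ValueError("TSS must not exceed TES after strand normalization")
        self.window_start = max(1, self.tss - self.flank)
        self.window_end = self.tes + self.flank


def novelty_score(
    region: GeneRegion,
    trait_term,
    catalog: pd.DataFrame,
    scheme: str,
    index: TermIndex | None = None,
) -> int:
    """1 when a catalog association already covers this gene-trait, else 0.

    A catalog row counts when it lies within the gene's window on the same
    chromosome AND its trait matches ``trait_term`` under ``scheme``.  A zero
    therefore marks the pair as novel relative to the catalog.
    """
    sub = catalog[
        (catalog["chrom"].astype(str) == str(region.chrom))
        & (catalog["pos"] >= region.window_start)
        & (catalog["pos"] <= region.window_end)
    ]
    for _, row in sub.iterrows():
        if match(trait_term, row, scheme, index=index):
            return 1
    return 0
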