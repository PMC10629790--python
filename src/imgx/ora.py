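"""Generic over-representation analysis of annotated term sets, with a
dictionary-based summarization of significant terms into broad categories.

Annotation sets are file inputs (GMT), never fetched from a live service, so
results are reproducible against a fixed annotation snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .enrichment import bh_adjust, hypergeom_overlap

__all__ = [
    "AnnotationSet",
    "CategorySummary",
    "read_gmt",
    "ora_test",
    "summarize_categories",
]


@dataclass
class AnnotationSet:
    """term id -> gene set, with optional human-readable term names."""

    sets: dict[str, set[str]]
    names: dict[str, str] | None = None

    def __post_init__(self) -> None:
        empty = [t for t, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty annotation sets: {empty[:10]}")


@dataclass
class CategorySummary:
    counts: pd.Series  # category -> number of significant terms
    proportions: pd.Series


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT file: term<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term, desc, genes = parts[0], parts[1], parts[2:]
        sets[term] = {g for g in genes if g}
        names[term] = desc
    return AnnotationSet(sets=sets, names=names)


def ora_test(
    target: list[str] | set[str],
    annotations: AnnotationSet,
    universe: list[str] | set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a target list in each term.

    Term genes are intersected with the universe first; p-values are BH
    adjusted across tested terms, significance at adjusted p < alpha.
    Columns: k, K, n, N, p, p_adj, significant.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    t = set(target)
    if not t <= uni:
        raise ValueError(f"target genes outside universe: {sorted(t - uni)[:10]}")
    rows = []
    for term in sorted(annotations.sets):
        term_genes = annotations.sets[term] & uni
        if not term_genes:
            continue
        res = hypergeom_overlap(t, term_genes, uni)
        rows.append((term, res.k, res.K, res.n, res.N, res.p))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]).set_index("term")
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["p_adj"] < alpha
    return out


def summarize_categories(
    significant_terms: list[str], dictionary: dict[str, str]
) -> CategorySummary:
    """Count significant terms per broad category.

    Terms missing from the dictionary fall into "uncategorized".  Proportions
    are counts over the number of significant terms; an empty input yields an
    empty summary.
    """
    if not significant_terms:
        empty = pd.Series(dtype=int)
        return CategorySummary(counts=empty, proportions=empty.astype(float))
    cats = [dictionary.get(t, "uncategorized") for t in significant_terms]
    counts = pd.Series(cats).value_counts().sort_index()
    return CategorySummary(counts=counts, proportions=counts / counts.sum())
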