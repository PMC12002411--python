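"""Obesity/drug DEG reversal classification and pathway enrichment.

Builds the four DEG categories (obesity up/down, drug up/down), their reversed
intersections, exclusive UpSet intersection counts, one-sided Fisher pathway
enrichment with a scaled overlap enrichment score, and per-pathway mean log2
fold changes for dot-plot summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

CATEGORIES = ("ob_up", "ob_down", "rosi_up", "rosi_down")


@dataclass
class ReversalSets:
    """The four DEG categories and their reversed intersections."""

    ob_up: set[str]
    ob_down: set[str]
    rosi_up: set[str]
    rosi_down: set[str]

    @property
    def reversed_up(self) -> set[str]:
        """Up in obesity and brought down by the drug."""
        return self.ob_up & self.rosi_down

    @property
    def reversed_down(self) -> set[str]:
        """Down in obesity and brought up by the drug."""
        return self.ob_down & self.rosi_up

    def as_dict(self) -> dict[str, set[str]]:
        return {c: getattr(self, c) for c in CATEGORIES}


def classify_reversal(de_ob: pd.DataFrame, de_rosi: pd.DataFrame,
                      fdr: float = 0.05) -> ReversalSets:
    """Split significant DEGs of the two contrasts by sign and intersect.

    `de_ob` is the obese-vs-lean DETable and `de_rosi` the drug-vs-obese-
    vehicle DETable. Both must share a gene universe (tested-gene overlap is
    allowed to differ because of the per-contrast pre-filters, but identifiers
    must be drawn from one namespace).
    """
    genes_ob = set(de_ob["gene"])
    genes_rosi = set(de_rosi["gene"])
    if genes_ob and genes_rosi and not (genes_ob & genes_rosi):
        mismatches = sorted(genes_ob)[:10]
        raise ValueError(
            "DE tables share no gene identifiers; first mismatches: "
            f"{mismatches}")

    def split(de: pd.DataFrame) -> tuple[set[str], set[str]]:
        sig = de[de["padj"] < fdr]
        return (set(sig.loc[sig["log2FC"] > 0, "gene"]),
                set(sig.loc[sig["log2FC"] < 0, "gene"]))

    ob_up, ob_down = split(de_ob)
    rosi_up, rosi_down = split(de_rosi)
    return ReversalSets(ob_up, ob_down, rosi_up, rosi_down)


def upset_counts(sets: ReversalSets) -> pd.DataFrame:
    """Exclusive intersection cardinalities over the four categories.

    Each gene is counted in exactly one combination (standard UpSet
    semantics), so the counts sum to the size of the union. Only non-empty
    combinations are returned, sorted by decreasing count.
    """
    named = sets.as_dict()
    rows = []
    for r in range(len(CATEGORIES), 0, -1):
        for combo in combinations(CATEGORIES, r):
            inside = set.intersection(*(named[c] for c in combo))
            outside = set.union(set(), *(named[c] for c in CATEGORIES
                                         if c not in combo))
            exclusive = inside - outside
            if exclusive:
                rows.append({"categories": "&".join(combo),
                             "degree": r, "count": len(exclusive)})
    df = pd.DataFrame(rows, columns=["categories", "degree", "count"])
    return df.sort_values("count", ascending=False,
                          kind="mergesort").reset_index(drop=True)


def enrichment_score(overlap: int, set_size: int, pathway_size: int,
                     scale: int = 20000) -> float:
    """Scaled overlap score: (overlap / set_size) * scale / pathway_size.

    `scale` is 20,000 for the single-cell analysis and the number of detected
    genes for the bulk variant.
    """
    if set_size <= 0 or pathway_size <= 0:
        raise ValueError("set_size and pathway_size must be positive")
    return overlap / set_size * scale / pathway_size


def fisher_pvalue(overlap, set_size, pathway_size, universe_size):
    """One-sided (enrichment) Fisher exact p for the 2x2 overlap table.

    Computed as the hypergeometric survival function P(X >= overlap) with X ~
    Hypergeom(universe_size, pathway_size, set_size), which is the exact
    one-sided Fisher tail. Accepts scalars or aligned arrays.
    """
    p = stats.hypergeom.sf(np.asarray(overlap) - 1, universe_size,
                           pathway_size, set_size)
    return float(p) if np.isscalar(overlap) else np.asarray(p)


def fisher_enrichment(genes: set[str], collection: dict[str, set[str]],
                      universe: set[str], fdr: float = 0.05,
                      scale: int = 20000,
                      de: pd.DataFrame | None = None,
                      de_secondary: pd.DataFrame | None = None) -> pd.DataFrame:
    """One-sided Fisher enrichment of `genes` against a gene-set collection.

    Pathways are intersected with `universe` before testing, and `genes` must
    be a subset of the universe. BH correction is applied across pathways.
    Optional DETables attach per-pathway mean log2FC of the overlapping DEGs
    (two contrasts for the dual-colour dot plot).
    """
    if not genes <= universe:
        extra = sorted(genes - universe)[:10]
        raise ValueError(f"genes outside the universe: {extra}")
    if not genes:
        warnings.warn("empty gene list; enrichment result is empty",
                      stacklevel=2)
        return pd.DataFrame(columns=["pathway", "overlap", "pathway_size",
                                     "p", "padj", "es", "mean_log2fc_a",
                                     "mean_log2fc_b", "significant"])
    rows = []
    for name, members in collection.items():
        pw = members & universe
        if not pw:
            continue
        ov = genes & pw
        rows.append({
            "pathway": name,
            "overlap": len(ov),
            "pathway_size": len(pw),
            "p": fisher_pvalue(len(ov), len(genes), len(pw), len(universe)),
            "es": enrichment_score(len(ov), len(genes), len(pw), scale),
            "mean_log2fc_a": pathway_mean_log2fc(ov, de),
            "mean_log2fc_b": pathway_mean_log2fc(ov, de_secondary),
        })
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"])
    df["significant"] = df["padj"] < fdr
    cols = ["pathway", "overlap", "pathway_size", "p", "padj", "es",
            "mean_log2fc_a", "mean_log2fc_b", "significant"]
    return df[cols].sort_values("p", kind="mergesort").reset_index(drop=True)


def pathway_mean_log2fc(pathway_genes: set[str],
                        de: pd.DataFrame | None) -> float:
    """Mean log2FC over significant DEGs inside a pathway.

    Undefined (NaN) when no significant DEG overlaps the pathway — missing is
    reported, never coerced to zero.
    """
    if de is None:
        return np.nan
    sig = de[de["significant"] & de["gene"].isin(pathway_genes)]
    if sig.empty:
        return np.nan
    return float(sig["log2FC"].mean())
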