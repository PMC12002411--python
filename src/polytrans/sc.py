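"""Single-cell QC filtering and Wilcoxon differential expression.

Cells are filtered on mitochondrial fraction, UMI count and detected-gene
count; genes are tested between labelled groups with a two-sided Wilcoxon
rank-sum test on log-normalised expression after percent-expressed and
fold-change pre-filters, with BH correction over the tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import EXACT_MAX_N, bh_adjust, rank_sum_test, rank_sum_test_matrix

DE_COLUMNS = ["gene", "log2FC", "pct_a", "pct_b", "p", "padj", "significant"]


@dataclass
class CellMatrix:
    """Cell x gene integer counts with per-cell metadata.

    `cells` must carry columns group, cell_type, umi, n_genes, mito_frac and
    have one row per matrix row.
    """

    counts: np.ndarray
    cells: pd.DataFrame
    genes: pd.Index

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes")
        missing = {"group", "cell_type", "umi", "n_genes", "mito_frac"} \
            - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell metadata missing columns: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def subset_cells(self, mask) -> "CellMatrix":
        mask = np.asarray(mask)
        return CellMatrix(self.counts[mask], self.cells.loc[mask].copy(),
                          self.genes)

    def normalized(self, scale: float = 1e4) -> np.ndarray:
        """log1p of counts scaled to `scale` per cell (CP10K by default)."""
        depth = self.counts.sum(axis=1, keepdims=True).astype(float)
        depth[depth == 0] = 1.0
        return np.log1p(self.counts / depth * scale)


def qc_filter_cells(matrix: CellMatrix, mito_max: float = 0.25,
                    umi_range=(700, 22000), gene_range=(200, 6000)):
    """Retain cells with mito fraction strictly below `mito_max` and UMI /
    detected-gene counts inside the closed intervals `umi_range` and
    `gene_range`.

    Returns (filtered CellMatrix, removal report dict with per-criterion
    counts). An empty result warns rather than fails.
    """
    md = matrix.cells
    pass_mito = md["mito_frac"].values < mito_max
    pass_umi = (md["umi"].values >= umi_range[0]) & \
        (md["umi"].values <= umi_range[1])
    pass_genes = (md["n_genes"].values >= gene_range[0]) & \
        (md["n_genes"].values <= gene_range[1])
    keep = pass_mito & pass_umi & pass_genes
    report = {
        "n_input": matrix.n_cells,
        "n_kept": int(keep.sum()),
        "removed_mito": int((~pass_mito).sum()),
        "removed_umi": int((~pass_umi).sum()),
        "removed_genes": int((~pass_genes).sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("QC filtering removed every cell", stacklevel=2)
    return matrix.subset_cells(keep), report


def _de_between(norm_a: np.ndarray, norm_b: np.ndarray, raw_a: np.ndarray,
                raw_b: np.ndarray, genes: pd.Index, min_frac: float,
                min_fold: float | None, min_logfc: float | None,
                fdr: float, positive_only: bool = False) -> pd.DataFrame:
    """Shared filter + Wilcoxon + BH engine for group DE and marker tests."""
    pct_a = (raw_a > 0).mean(axis=0)
    pct_b = (raw_b > 0).mean(axis=0)
    if positive_only:
        frac_ok = pct_a >= min_frac
    else:
        frac_ok = (pct_a >= min_frac) | (pct_b >= min_frac)

    # fold change on the natural scale of mean log-normalised expression,
    # with pseudocount 1 in numerator and denominator
    num = np.expm1(norm_a.mean(axis=0)) + 1.0
    den = np.expm1(norm_b.mean(axis=0)) + 1.0
    log2fc = np.log2(num / den)
    if min_fold is not None:
        fold = np.maximum(num / den, den / num)
        fc_ok = fold >= min_fold
    else:
        lfc = log2fc if positive_only else np.abs(log2fc)
        fc_ok = lfc >= min_logfc
    tested = frac_ok & fc_ok
    idx = np.flatnonzero(tested)

    pvals = np.full(idx.size, np.nan)
    if idx.size:
        small = norm_a.shape[0] <= EXACT_MAX_N and norm_b.shape[0] <= EXACT_MAX_N
        if small:
            for j, g in enumerate(idx):
                pvals[j] = rank_sum_test(norm_a[:, g], norm_b[:, g])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pvals = rank_sum_test_matrix(norm_a[:, idx], norm_b[:, idx])
            pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    padj = bh_adjust(pvals)
    out = pd.DataFrame({
        "gene": genes[idx],
        "log2FC": log2fc[idx],
        "pct_a": pct_a[idx],
        "pct_b": pct_b[idx],
        "p": pvals,
        "padj": padj,
        "significant": padj < fdr,
    })
    return out.reset_index(drop=True)


def group_de(matrix: CellMatrix, group_a: str, group_b: str,
             min_frac: float = 0.10, min_fold: float = 1.1,
             fdr: float = 0.05) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two cell groups.

    Genes must be detected in at least `min_frac` of cells in one of the two
    groups and show at least `min_fold` fold change (either direction, on the
    natural scale, boundary inclusive) between group means of normalised
    expression. Returns a DETable DataFrame (columns: gene, log2FC, pct_a,
    pct_b, p, padj, significant); log2FC is group_a relative to group_b.
    """
    labels = matrix.cells["group"].values
    for g in (group_a, group_b):
        n = int((labels == g).sum())
        if n < 3:
            raise ValueError(f"group {g!r} has {n} cells; at least 3 required")
    norm = matrix.normalized()
    in_a = labels == group_a
    in_b = labels == group_b
    return _de_between(norm[in_a], norm[in_b], matrix.counts[in_a],
                       matrix.counts[in_b], matrix.genes, min_frac,
                       min_fold, None, fdr)


def cluster_markers(matrix: CellMatrix, cluster_labels=None,
                    min_frac: float = 0.10, min_logfc: float = 0.25,
                    fdr: float = 0.05) -> dict[str, pd.DataFrame]:
    """One-vs-rest Wilcoxon marker test per cluster.

    Candidate markers must be expressed in at least `min_frac` of the cells in
    the cluster of interest and upregulated by at least `min_logfc` (log2)
    versus all other cells. Singleton clusters are skipped with a warning.
    Returns {cluster: DETable}, sorted by adjusted p.
    """
    labels = np.asarray(cluster_labels if cluster_labels is not None
                        else matrix.cells["cell_type"].values)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("marker testing requires at least 2 clusters")
    norm = matrix.normalized()
    out: dict[str, pd.DataFrame] = {}
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 2:
            warnings.warn(f"cluster {cl!r} is a singleton; skipped",
                          stacklevel=2)
            continue
        table = _de_between(norm[mask], norm[~mask], matrix.counts[mask],
                            matrix.counts[~mask], matrix.genes, min_frac,
                            None, min_logfc, fdr, positive_only=True)
        out[cl] = table.sort_values(["padj", "p"],
                                    kind="mergesort").reset_index(drop=True)
    return out
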