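"""Hexamer enrichment, PSSM construction and exact-p motif scanning.

Overlapping k-mer windows (length 6, step 1) are counted per sequence set,
foreground-vs-background enrichment is a pooled two-proportion z-test
(enriched at z > 3), enriched hexamers are stacked into a position weight
matrix, and sequences are scanned with exact tail p-values obtained by full
enumeration of the 4^6 = 4096 background words — no approximation is needed
at this motif width. Scanning is single strand (mRNA 5'->3').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
K = 6


@dataclass
class KmerCounts:
    """Overlapping-window hexamer counts for one sequence set."""

    counts: pd.Series            # hexamer -> occurrence count
    total_windows: int           # sum over sequences of max(0, len - 5)
    skipped_windows: int = 0     # windows containing N
    label: str = ""
    region: str = "5UTR"

    @property
    def frequencies(self) -> pd.Series:
        return self.counts / self.counts.sum()


@dataclass
class MotifModel:
    """6-position x 4-base PSSM with background composition.

    `counts` are raw base tallies of the stacked hexamers; `frequencies`
    include the pseudocount; `weights` are log2 odds versus the background
    base probabilities.
    """

    counts: np.ndarray
    frequencies: np.ndarray
    weights: np.ndarray
    background: np.ndarray
    pseudocount: float = 1.0
    hexamers: list[str] = field(default_factory=list)


def count_kmers(seqs: dict[str, str] | list[str], k: int = K, step: int = 1,
                label: str = "", region: str = "5UTR") -> KmerCounts:
    """Count overlapping k-mers across a sequence set.

    Windows containing bases outside {A,C,G,T} (e.g. N) are skipped and
    tallied separately; they do not enter `total_windows`.
    """
    if isinstance(seqs, dict):
        seqs = list(seqs.values())
    if not seqs:
        raise ValueError("empty sequence set")
    counts: dict[str, int] = {}
    total = 0
    skipped = 0
    valid = set(BASES)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, max(0, len(seq) - k + 1), step):
            word = seq[i:i + k]
            if set(word) - valid:
                skipped += 1
                continue
            counts[word] = counts.get(word, 0) + 1
            total += 1
    series = pd.Series(counts, dtype=float).sort_index()
    return KmerCounts(counts=series, total_windows=total,
                      skipped_windows=skipped, label=label, region=region)


def kmer_enrichment_z(fg: KmerCounts, bg: KmerCounts,
                      z_min: float = 3.0) -> pd.DataFrame:
    """Pooled two-proportion z per hexamer, foreground vs background.

    z = (p_fg - p_bg) / sqrt(p_hat (1 - p_hat) (1/N_fg + 1/N_bg)) with the
    pooled proportion p_hat over window totals. Hexamers absent from both
    sets get z = 0 by convention. Enriched means z > `z_min`. The statistic
    is antisymmetric under swapping the two sets.
    """
    if fg.total_windows == 0 or bg.total_windows == 0:
        raise ValueError("both sets must contain at least one valid window")
    hexamers = fg.counts.index.union(bg.counts.index)
    c_fg = fg.counts.reindex(hexamers, fill_value=0.0)
    c_bg = bg.counts.reindex(hexamers, fill_value=0.0)
    n_fg, n_bg = fg.total_windows, bg.total_windows
    p_fg = c_fg / n_fg
    p_bg = c_bg / n_bg
    pooled = (c_fg + c_bg) / (n_fg + n_bg)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_fg + 1.0 / n_bg))
        z = (p_fg - p_bg) / se
    z = z.where(np.isfinite(z), 0.0)
    out = pd.DataFrame({"hexamer": hexamers, "count_fg": c_fg.values,
                        "count_bg": c_bg.values, "z": z.values,
                        "enriched": z.values > z_min})
    return out.sort_values("z", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def build_pssm(hexamers, pseudocount: float = 1.0,
               background=None) -> MotifModel:
    """Stack enriched hexamers (aligned at position 1) into a PSSM.

    Frequencies use `pseudocount` added to every cell; weights are
    log2(frequency / background probability).
    """
    hexamers = list(hexamers)
    if not hexamers:
        raise ValueError("at least one hexamer is required")
    if any(len(h) != K for h in hexamers):
        raise ValueError("all hexamers must have length 6")
    if any(set(h.upper()) - set(BASES) for h in hexamers):
        raise ValueError("hexamers must be over {A,C,G,T}")
    background = (np.full(4, 0.25) if background is None
                  else np.asarray(background, dtype=float))
    if background.shape != (4,) or abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must be a length-4 probability vector")
    counts = np.zeros((K, 4))
    for h in hexamers:
        for pos, base in enumerate(h.upper()):
            counts[pos, _BASE_INDEX[base]] += 1
    freq = (counts + pseudocount) / (counts + pseudocount).sum(axis=1,
                                                               keepdims=True)
    with np.errstate(divide="ignore"):
        weights = np.log2(freq / background[None, :])
    return MotifModel(counts=counts, frequencies=freq, weights=weights,
                      background=background, pseudocount=pseudocount,
                      hexamers=[h.upper() for h in hexamers])


def base_composition(seqs: dict[str, str] | list[str]) -> np.ndarray:
    """Order-0 background: pooled base probabilities of a sequence set."""
    if isinstance(seqs, dict):
        seqs = list(seqs.values())
    tallies = np.zeros(4)
    for seq in seqs:
        for base in seq.upper():
            if base in _BASE_INDEX:
                tallies[_BASE_INDEX[base]] += 1
    if tallies.sum() == 0:
        raise ValueError("no A/C/G/T bases in the sequence set")
    return tallies / tallies.sum()


def _score_distribution(model: MotifModel):
    """Exact null score distribution over all 4096 words.

    Returns (scores sorted ascending, tail probability P(S >= score) aligned
    with the sorted scores).
    """
    idx = np.array(list(product(range(4), repeat=K)))   # 4096 x 6
    scores = model.weights[np.arange(K)[None, :], idx].sum(axis=1)
    probs = model.background[idx].prod(axis=1)
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    # tail prob of >= each sorted score
    tail = np.cumsum(probs[order][::-1])[::-1]
    return s_sorted, tail


def score_word(word: str, model: MotifModel) -> float:
    return float(sum(model.weights[i, _BASE_INDEX[b]]
                     for i, b in enumerate(word.upper())))


def scan_sites(seq: str, model: MotifModel, p_max: float = 0.05,
               _dist=None) -> pd.DataFrame:
    """Score every hexamer window of `seq`; exact background tail p-values.

    p = P(score >= s) under the order-0 background model, from the full
    4096-word enumeration. Windows containing non-ACGT bases are skipped.
    Returns all windows with columns start / score / p / significant
    (significant means p < `p_max`).
    """
    seq = seq.upper()
    if len(seq) < K:
        raise ValueError("sequence shorter than the motif width")
    s_sorted, tail = _score_distribution(model) if _dist is None else _dist
    rows = []
    for start in range(len(seq) - K + 1):
        word = seq[start:start + K]
        if set(word) - set(BASES):
            continue
        s = score_word(word, model)
        # rightmost index with sorted score < s - tol: tail prob at that point
        j = np.searchsorted(s_sorted, s - 1e-9, side="left")
        p = float(tail[j]) if j < tail.size else 0.0
        rows.append({"start": start, "score": s, "p": p,
                     "significant": p < p_max})
    return pd.DataFrame(rows, columns=["start", "score", "p", "significant"])


def scan_many(seqs: dict[str, str], model: MotifModel,
              p_max: float = 0.05) -> dict[str, pd.DataFrame]:
    """Scan a set of sequences sharing one precomputed null distribution."""
    dist = _score_distribution(model)
    return {name: scan_sites(seq, model, p_max, _dist=dist)
            for name, seq in seqs.items()}


def feature_map(sites: dict[str, pd.DataFrame]) -> dict[str, list[int]]:
    """Per-transcript ordered significant-site start positions.

    Transcripts without significant sites are kept with empty lists.
    """
    return {tx: sorted(df.loc[df["significant"], "start"].astype(int).tolist())
            for tx, df in sites.items()}


def score_correlation(z_a: pd.DataFrame, z_b: pd.DataFrame) -> float:
    """Pearson correlation of enrichment z over the shared hexamers.

    Used as the background-robustness check: enrichment tables computed
    against different background sets should correlate strongly.
    """
    a = z_a.set_index("hexamer")["z"]
    b = z_b.set_index("hexamer")["z"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared hexamers; >= 3 required")
    r, _ = stats.pearsonr(a.loc[shared], b.loc[shared])
    return float(r)
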