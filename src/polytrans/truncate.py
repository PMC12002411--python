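"""Truncated-5'UTR candidate design from significant motif sites.

100-nt sliding windows (step 1) count the significant sites starting inside
them; windows with more than one site are "functional"; runs of at least two
adjacent functional windows merge into candidate truncated 5'UTRs. Isolated
functional windows are reported separately, never emitted as candidates.
All coordinates are 0-based, end-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WindowSet:
    """Sliding windows over one 5'UTR with per-window site counts."""

    transcript: str
    utr_length: int
    window: int
    step: int
    starts: np.ndarray            # window start positions
    site_counts: np.ndarray       # significant sites starting in each window
    functional: np.ndarray        # site_counts > min_sites_exclusive
    short_utr: bool = False       # UTR shorter than the window length
    sites: list[int] = field(default_factory=list)


@dataclass
class TruncatedUTR:
    """A candidate truncated 5'UTR merged from adjacent functional windows."""

    transcript: str
    start: int
    end: int                      # end-exclusive; clipped to the UTR length
    n_windows: int
    n_sites: int


def functional_windows(sites, utr_length: int, window: int = 100,
                       step: int = 1, min_sites_exclusive: int = 1,
                       transcript: str = "") -> WindowSet:
    """Count significant sites per sliding window and flag functional ones.

    `sites` is a list of significant-site start positions (or a scan table
    with a significant column). A site belongs to window [s, s+window) when
    its start lies inside. Functional requires strictly more than
    `min_sites_exclusive` sites. UTRs shorter than the window yield a single
    whole-UTR window, flagged via `short_utr`.
    """
    if isinstance(sites, pd.DataFrame):
        sites = sites.loc[sites["significant"], "start"].astype(int).tolist()
    sites = sorted(int(s) for s in sites)
    if sites and sites[0] < 0:
        raise ValueError("negative site positions")
    if utr_length < window:
        starts = np.array([0])
        win_len = utr_length
        short = True
    else:
        starts = np.arange(0, utr_length - window + 1, step)
        win_len = window
        short = False
    arr = np.asarray(sites)
    counts = np.array([
        int(((arr >= s) & (arr < s + win_len)).sum()) if arr.size else 0
        for s in starts])
    return WindowSet(transcript=transcript, utr_length=utr_length,
                     window=window, step=step, starts=starts,
                     site_counts=counts,
                     functional=counts > min_sites_exclusive,
                     short_utr=short, sites=sites)


def merge_windows(windows: WindowSet):
    """Merge runs of adjacent functional windows into candidate regions.

    Adjacent means consecutive start positions (`step` apart). A run of
    functional starts s1..s2 yields [s1, s2 + window), clipped to the UTR;
    runs of a single window are excluded from the candidates (at least two
    adjacent functional windows are required) and returned separately.

    Returns (candidates: list[TruncatedUTR], isolated: list[int] of isolated
    functional window starts).
    """
    starts = windows.starts[windows.functional]
    candidates: list[TruncatedUTR] = []
    isolated: list[int] = []
    if starts.size == 0:
        return candidates, isolated
    arr = np.asarray(windows.sites)
    run_start = prev = int(starts[0])
    run_len = 1
    for s in list(starts[1:]) + [None]:
        if s is not None and int(s) - prev == windows.step:
            prev = int(s)
            run_len += 1
            continue
        end = min(prev + windows.window, windows.utr_length)
        if run_len >= 2:
            n_sites = int(((arr >= run_start) & (arr < end)).sum()) \
                if arr.size else 0
            candidates.append(TruncatedUTR(
                transcript=windows.transcript, start=run_start, end=end,
                n_windows=run_len, n_sites=n_sites))
        else:
            isolated.append(run_start)
        if s is not None:
            run_start = prev = int(s)
            run_len = 1
    return candidates, isolated


def design_truncated_utrs(site_map: dict[str, list[int]],
                          utr_lengths: dict[str, int], window: int = 100,
                          step: int = 1,
                          min_sites_exclusive: int = 1) -> pd.DataFrame:
    """Run the window/merge design across transcripts.

    `site_map` is a feature map ({tx: significant-site starts}); returns a
    table with one row per candidate plus `isolated` rows for lone functional
    windows (kind column distinguishes the two).
    """
    rows = []
    for tx, sites in site_map.items():
        ws = functional_windows(sites, utr_lengths[tx], window, step,
                                min_sites_exclusive, transcript=tx)
        candidates, isolated = merge_windows(ws)
        for c in candidates:
            rows.append({"transcript": tx, "kind": "candidate",
                         "start": c.start, "end": c.end,
                         "n_windows": c.n_windows, "n_sites": c.n_sites,
                         "short_utr": ws.short_utr})
        for s in isolated:
            rows.append({"transcript": tx, "kind": "isolated", "start": s,
                         "end": min(s + window, ws.utr_length),
                         "n_windows": 1, "n_sites": int(ws.site_counts[
                             np.searchsorted(ws.starts, s)]),
                         "short_utr": ws.short_utr})
    return pd.DataFrame(rows, columns=["transcript", "kind", "start", "end",
                                       "n_windows", "n_sites", "short_utr"])
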