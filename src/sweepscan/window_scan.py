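"""Aggregate per-site iHS into fixed windows and call top-percentile regions.

Sites are binned into non-overlapping 50 kb windows tiling each chromosome
from position 1; a window's statistic is the mean of |standardized iHS| over
its valid sites (the signed mean is also reported for transparency).
Windows with too few scored SNPs are discarded, and the top fraction
(default 1%) of the survivors by mean |iHS| are called candidate selected
regions.

Window labels are printed 1-based with ``end = start + window_size`` (the
convention used in cattle selection scans, e.g. ``chr5:58800001-58850001``);
internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ehh_ihs import IHSScore


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int        # 1-based label
    end: int          # label convention: start + window_size
    n_snps: int
    window_stat: float    # mean of |ihs_std|
    signed_stat: float    # |mean of ihs_std|
    window_size: int = 50_000

    @property
    def interval0(self) -> tuple[int, int]:
        """Internal 0-based half-open interval."""
        return self.start - 1, self.start - 1 + self.window_size

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SelectedRegion:
    window: Window
    rank: int              # 1 = highest window_stat
    threshold: float       # smallest selected window_stat

    @property
    def chrom(self) -> str:
        return self.window.chrom

    @property
    def interval0(self) -> tuple[int, int]:
        return self.window.interval0

    @property
    def label(self) -> str:
        return self.window.label


def bin_scores(
    scores: Sequence[IHSScore], window_size: int = 50_000
) -> list[Window]:
    """Group valid standardized scores into fixed windows.

    A site at 1-based position P belongs to window index
    ``floor((P - 1) / window_size)``; empty windows are omitted.  Every
    valid score lands in exactly one window, so window SNP counts sum to
    the number of valid scores.
    """
    buckets: dict[tuple[str, int], list[float]] = {}
    for s in scores:
        if not s.valid:
            continue
        idx = (s.position - 1) // window_size
        buckets.setdefault((s.chrom, idx), []).append(s.ihs_std)
    windows = []
    for (chrom, idx), vals in sorted(buckets.items()):
        arr = np.asarray(vals)
        start = idx * window_size + 1
        windows.append(
            Window(
                chrom=chrom,
                start=start,
                end=start + window_size,
                n_snps=arr.size,
                window_stat=float(np.abs(arr).mean()),
                signed_stat=float(abs(arr.mean())),
                window_size=window_size,
            )
        )
    return windows


def filter_windows(windows: Sequence[Window], min_snps: int = 10) -> list[Window]:
    """Discard windows with fewer than ``min_snps`` scored SNPs."""
    return [w for w in windows if w.n_snps >= min_snps]


def select_top(
    windows: Sequence[Window], fraction: float = 0.01
) -> list[SelectedRegion]:
    """Call the top ``fraction`` of windows by mean |iHS|.

    Exactly ``k = floor(fraction * len(windows))`` regions are returned,
    ranked by descending window statistic; ties at the selection boundary
    are broken by (chrom, start) order with a warning.  The realized
    threshold is the smallest selected statistic.
    """
    k = int(np.floor(fraction * len(windows)))
    if k == 0:
        warnings.warn(
            f"top fraction {fraction} of {len(windows)} windows selects nothing",
            stacklevel=2,
        )
        return []
    ordered = sorted(windows, key=lambda w: (-w.window_stat, w.chrom, w.start))
    boundary = ordered[k - 1].window_stat
    if len(ordered) > k and ordered[k].window_stat == boundary:
        warnings.warn(
            f"tie at the selection boundary (stat={boundary:.6g}); "
            "broken by (chrom, start) order",
            stacklevel=2,
        )
    selected = ordered[:k]
    threshold = selected[-1].window_stat
    return [
        SelectedRegion(window=w, rank=r + 1, threshold=threshold)
        for r, w in enumerate(selected)
    ]


def windows_frame(
    windows: Sequence[Window], selected: Sequence[SelectedRegion] = ()
):
    """Windows as a pandas DataFrame with selection flags and ranks."""
    import pandas as pd

    rank = {(s.chrom, s.window.start): s.rank for s in selected}
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "mean_abs_ihs": [w.window_stat for w in windows],
            "abs_mean_ihs": [w.signed_stat for w in windows],
            "selected": [(w.chrom, w.start) in rank for w in windows],
            "rank": [rank.get((w.chrom, w.start), 0) for w in windows],
        }
    )
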