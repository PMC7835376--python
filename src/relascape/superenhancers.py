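"""ROSE-style super-enhancer calling and inflection-point ranking.

Peaks closer than a stitch distance (12,500 bp by default, the ROSE default)
are merged into stitched regions, ranked by aggregate signal, and split into
typical vs super enhancers at the point where, after min-max scaling both
ranks and signals to [0, 1], a line of slope 1 is tangent to the sorted
signal curve.  For convex non-decreasing curves that tangency is the argmin
of (scaled signal - scaled rank); the smallest index wins ties, which keeps
the call deterministic.  The same cutoff construction is reused to define
"top-ranked" individual peaks from per-peak signal, and a simple
constraint-score ranking rounds the module out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, Peak, PeakSet
from .tracks import SignalTrack

DEFAULT_STITCH_DISTANCE = 12_500

__all__ = [
    "StitchedRegion",
    "RankedCutoff",
    "stitch_peaks",
    "rank_and_cutoff",
    "call_superenhancers",
    "top_ranked_peaks",
    "rank_by_constraint",
]


@dataclass
class StitchedRegion:
    region_id: str
    interval: GenomicInterval
    constituents: list[str]
    signal: float = 0.0
    rank: int = 0  # ascending by signal after ranking
    is_super: bool = False


@dataclass
class RankedCutoff:
    """Inflection cutoff on an ascending-sorted signal vector."""

    cutoff_index: int  # index into the ascending sort
    cutoff_signal: float
    n: int
    degenerate: bool = False  # all signals equal: no cutoff exists
    scaled_rank: float = 0.0
    scaled_signal: float = 0.0


def stitch_peaks(
    peaks: PeakSet, stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> list[StitchedRegion]:
    """Transitively merge peaks whose gap (next.start - prev.end) is at most
    ``stitch_distance``; the region interval is the union span."""
    if stitch_distance < 0:
        raise ValueError("stitch distance must be >= 0")
    regions: list[StitchedRegion] = []
    current: list[Peak] = []

    def flush():
        if not current:
            return
        iv = GenomicInterval(current[0].chrom, current[0].start, current[-1].end)
        regions.append(
            StitchedRegion(
                region_id=f"region_{len(regions):05d}",
                interval=iv,
                constituents=[p.id for p in current],
            )
        )

    for p in peaks:  # PeakSet iterates in (chrom, start) order
        if current and (
            p.chrom != current[-1].chrom
            or p.start - current[-1].end > stitch_distance
        ):
            flush()
            current = []
        current.append(p)
    flush()
    return regions


def rank_and_cutoff(signals) -> RankedCutoff:
    """Slope-1 tangency cutoff on the min-max-scaled rank/signal curve.

    Signals are sorted ascending; x_i = i/(n-1), y_i = (s_i - min)/(max -
    min); the cutoff index is the smallest argmin of (y_i - x_i) and entries
    with signal strictly above the cutoff signal are "above".
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 signal values")
    lo, hi = s[0], s[-1]
    if hi == lo:
        return RankedCutoff(cutoff_index=n - 1, cutoff_signal=lo, n=n, degenerate=True)
    x = np.arange(n) / (n - 1)
    y = (s - lo) / (hi - lo)
    i_star = int(np.argmin(y - x))  # np.argmin returns the first minimum
    return RankedCutoff(
        cutoff_index=i_star,
        cutoff_signal=float(s[i_star]),
        n=n,
        scaled_rank=float(x[i_star]),
        scaled_signal=float(y[i_star]),
    )


def call_superenhancers(
    peaks: PeakSet,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    treatment: SignalTrack | None = None,
    control: SignalTrack | None = None,
) -> tuple[list[StitchedRegion], RankedCutoff]:
    """Stitch, quantify, rank and call super-enhancers.

    Region signal is the sum of treatment signal over the region minus the
    control signal (floored at 0).  Without a treatment track the constituent
    peaks' own signal values are summed, which matches tracks built to
    integrate to the peak signals.
    """
    regions = stitch_peaks(peaks, stitch_distance)
    by_id = peaks.by_id()
    for region in regions:
        if treatment is not None:
            sig = treatment.sum(region.interval)
        else:
            sig = sum(by_id[pid].signal for pid in region.constituents)
        if control is not None:
            sig -= control.sum(region.interval)
        region.signal = max(0.0, sig)
    cutoff = rank_and_cutoff([r.signal for r in regions])
    for rank, region in enumerate(sorted(regions, key=lambda r: (r.signal, r.region_id))):
        region.rank = rank
    if not cutoff.degenerate:
        for region in regions:
            region.is_super = region.signal > cutoff.cutoff_signal
    return regions, cutoff


def top_ranked_peaks(
    peaks_stim: PeakSet,
    signal_basal: SignalTrack,
    signal_stim: SignalTrack,
) -> tuple[set[str], set[str], RankedCutoff, RankedCutoff]:
    """Apply the inflection cutoff to per-peak signal in each condition.

    Every stimulated peak is scored by the summed basal and stimulated track
    signal over its own interval; peaks above the cutoff in a condition form
    that condition's top-ranked set.  Returns (top pre, top post, pre cutoff,
    post cutoff).
    """
    ids = peaks_stim.ids()
    pre = np.array([signal_basal.sum(p.interval) for p in peaks_stim])
    post = np.array([signal_stim.sum(p.interval) for p in peaks_stim])
    out = []
    cutoffs = []
    for scores in (pre, post):
        cut = rank_and_cutoff(scores)
        cutoffs.append(cut)
        if cut.degenerate:
            out.append(set())
        else:
            out.append(
                {pid for pid, sc in zip(ids, scores) if sc > cut.cutoff_signal}
            )
    return out[0], out[1], cutoffs[0], cutoffs[1]


def rank_by_constraint(
    peaks: PeakSet, constraint: SignalTrack, k: int
) -> set[str]:
    """Ids of the k peaks with highest length-weighted mean constraint score;
    ties broken by peak id for a stable, deterministic selection."""
    if k < 0:
        raise ValueError("k must be >= 0")
    scored = sorted(
        ((constraint.mean(p.interval), p.id) for p in peaks),
        key=lambda t: (-t[0], t[1]),
    )
    return {pid for _, pid in scored[:k]}
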