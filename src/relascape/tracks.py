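"""Step-function signal tracks (bedGraph) and summit-centred meta-profiles.

A :class:`SignalTrack` is a sparse per-chromosome step function; positions
not covered by any step have value 0, matching the bedGraph sparse
convention.  Tracks carry coverage (RPM), evolutionary-constraint scores or
nucleosome-occupancy values -- the summaries are the same in each case.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = ["SignalTrack", "summarize_track", "meta_profile"]


class SignalTrack:
    """Per-chromosome disjoint sorted steps ``[start, end) -> value``."""

    def __init__(self, steps: dict[str, tuple] | None = None, units: str = "RPM"):
        # steps: chrom -> (starts, ends, values) arrays
        self.units = units
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if steps:
            for chrom, (s, e, v) in steps.items():
                self._add_chrom(chrom, s, e, v)

    def _add_chrom(self, chrom, starts, ends, values) -> None:
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        v = np.asarray(values, dtype=float)
        if not (len(s) == len(e) == len(v)):
            raise ValueError("starts/ends/values length mismatch")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(e <= s):
            raise ValueError(f"{chrom}: empty or inverted step")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"{chrom}: overlapping steps")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{chrom}: non-finite values")
        self._steps[chrom] = (s, e, v)

    @classmethod
    def from_intervals(
        cls, records: list[tuple[str, int, int, float]], units: str = "RPM"
    ) -> "SignalTrack":
        per: dict[str, list[list]] = {}
        for chrom, s, e, v in records:
            per.setdefault(chrom, [[], [], []])
            per[chrom][0].append(s)
            per[chrom][1].append(e)
            per[chrom][2].append(v)
        return cls({c: tuple(cols) for c, cols in per.items()}, units=units)

    @classmethod
    def read_bedgraph(cls, path, units: str = "RPM") -> "SignalTrack":
        per: dict[str, list[list]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                per.setdefault(chrom, [[], [], []])
                per[chrom][0].append(int(s))
                per[chrom][1].append(int(e))
                per[chrom][2].append(float(v))
        return cls({c: tuple(cols) for c, cols in per.items()}, units=units)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._steps):
                s, e, v = self._steps[chrom]
                for i in range(len(s)):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{float(v[i])!r}\n")

    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def _overlap_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value * covered-bp over [start, end); uncovered bp are 0."""
        if chrom not in self._steps or end <= start:
            return 0.0
        s, e, v = self._steps[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float(np.dot(ov, v[lo:hi]))

    def sum(self, interval: GenomicInterval) -> float:
        return self._overlap_sum(interval.chrom, interval.start, interval.end)

    def mean(self, interval: GenomicInterval) -> float:
        return self.sum(interval) / interval.length

    def summarize(self, interval: GenomicInterval, stat: str = "mean") -> float:
        """Length-weighted summary of the track over one interval."""
        if stat == "mean":
            return self.mean(interval)
        if stat == "sum":
            return self.sum(interval)
        raise ValueError(f"unknown stat {stat!r} (use 'mean' or 'sum')")


def summarize_track(track: SignalTrack, interval: GenomicInterval, stat: str = "mean") -> float:
    """Length-weighted mean or sum of a track over one interval (module-level
    convenience for :meth:`SignalTrack.summarize`)."""
    return track.summarize(interval, stat)


def meta_profile(
    track: SignalTrack,
    anchors: list[tuple],
    flank: int,
    binsize: int,
) -> pd.DataFrame:
    """Average the track in fixed bins around a set of anchor positions.

    ``anchors`` are ``(chrom, position)`` or ``(chrom, position, strand)``
    tuples (typically peak summits); minus-strand anchors are mirrored.
    Returns a frame with columns ``bin_offset`` (left edge relative to the
    anchor), ``mean`` and ``sem`` where SEM = sample SD / sqrt(n anchors).
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if flank <= 0 or binsize <= 0 or flank % binsize != 0:
        raise ValueError("flank must be a positive multiple of binsize")
    nbins = 2 * flank // binsize
    offsets = np.arange(-flank, flank, binsize)
    values = np.zeros((len(anchors), nbins))
    for i, anchor in enumerate(anchors):
        chrom, pos = anchor[0], int(anchor[1])
        strand = anchor[2] if len(anchor) > 2 else "+"
        for j, off in enumerate(offsets):
            o = -off - binsize if strand == "-" else off
            start = pos + o
            if start + binsize <= 0:
                continue
            values[i, j] = track._overlap_sum(chrom, max(start, 0), start + binsize) / binsize
    mean = values.mean(axis=0)
    if len(anchors) > 1:
        sem = values.std(axis=0, ddof=1) / math.sqrt(len(anchors))
    else:
        sem = np.zeros(nbins)
    return pd.DataFrame({"bin_offset": offsets, "mean": mean, "sem": sem})
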