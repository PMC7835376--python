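"""Genomic intervals, peaks and exact overlap calling.

Everything downstream (conservation calling, mode classification,
super-enhancer stitching, enrichment counting) is built on the types in this
module.  Coordinates are 0-based, half-open throughout (BED convention);
peak summits are stored as absolute positions.  Peaks inside one
:class:`PeakSet` are required to be disjoint, which is what peak callers
emit -- pooled sets that violate this can be repaired with
``merge_overlaps=True`` at read time.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "ParseError",
    "read_narrowpeak",
    "write_narrowpeak",
    "intersect",
    "overlap_length",
]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals (0 if different chromosomes)."""
    return a.overlap_length(b)


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus a unique id, signal and summit.

    ``signal`` is the caller's quantification (RPM or read count) and
    ``summit`` the absolute position of maximal signal.
    """

    interval: GenomicInterval
    id: str
    signal: float
    summit: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("peak id must be non-empty")
        if self.signal < 0:
            raise ValueError(f"peak {self.id}: signal must be >= 0")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"peak {self.id}: summit {self.summit} outside "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PeakSet:
    """A sorted, disjoint collection of peaks from one species/assay/condition."""

    species: str
    assay: str
    condition: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species or not self.assay or not self.condition:
            raise ValueError("species, assay and condition must be non-empty")
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start))
        seen: set[str] = set()
        prev: Peak | None = None
        for p in self.peaks:
            if p.id in seen:
                raise ValueError(f"duplicate peak id {p.id!r}")
            seen.add(p.id)
            if prev is not None and prev.chrom == p.chrom and p.start < prev.end:
                raise ValueError(
                    f"peaks {prev.id} and {p.id} overlap; PeakSet requires "
                    "disjoint peaks (read with merge_overlaps=True to union)"
                )
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def by_id(self) -> dict[str, Peak]:
        return {p.id: p for p in self.peaks}

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def replace_peaks(self, peaks: list[Peak]) -> "PeakSet":
        return PeakSet(self.species, self.assay, self.condition, peaks)


def _merge_records(
    records: list[tuple[str, int, int, str, float, int]],
) -> list[tuple[str, int, int, str, float, int]]:
    """Union overlapping records; keeps the id/summit of the strongest one."""
    records = sorted(records, key=lambda r: (r[0], r[1]))
    merged: list[tuple[str, int, int, str, float, int]] = []
    for rec in records:
        if merged and merged[-1][0] == rec[0] and rec[1] < merged[-1][2]:
            c, s, e, pid, sig, summ = merged[-1]
            e = max(e, rec[2])
            if rec[4] > sig:
                pid, sig, summ = rec[3], rec[4], rec[5]
            merged[-1] = (c, s, e, pid, sig, summ)
        else:
            merged.append(rec)
    return merged


def read_narrowpeak(
    path,
    species: str = "unknown",
    assay: str = "other",
    condition: str = "stimulated",
    merge_overlaps: bool = False,
) -> PeakSet:
    """Read a narrowPeak (BED6+4) or BED6 file into a :class:`PeakSet`.

    narrowPeak column 10 is the summit offset from ``start``; an offset of
    ``-1`` (and any BED6 record) falls back to the interval midpoint.
    """
    records: list[tuple[str, int, int, str, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                signal = float(fields[6]) if len(fields) >= 10 else float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(fields) >= 10:
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad summit offset") from exc
                summit = start + offset if offset >= 0 else (start + end) // 2
            else:
                summit = (start + end) // 2
            if not (start <= summit < end):
                raise ParseError(
                    f"{path}:{lineno}: summit {summit} outside interval "
                    f"{chrom}:{start}-{end}"
                )
            if signal < 0:
                signal = 0.0
            records.append((chrom, start, end, name, signal, summit))
    if merge_overlaps:
        records = _merge_records(records)
    peaks = [
        Peak(GenomicInterval(c, s, e), pid, sig, summ)
        for c, s, e, pid, sig, summ in records
    ]
    return PeakSet(species, assay, condition, peaks)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    """Write a PeakSet in narrowPeak format (signal in column 7, summit offset
    in column 10)."""
    with open(path, "w") as fh:
        for p in peakset:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.id,
                        "0",
                        p.interval.strand,
                        repr(p.signal),
                        "-1",
                        "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


def intersect(
    a: PeakSet, b: PeakSet, min_overlap: int = 1
) -> dict[str, list[str]]:
    """Map each peak id in ``a`` to the ids of peaks in ``b`` overlapping it
    by at least ``min_overlap`` bp.

    Peaks in both sets are disjoint and sorted (PeakSet invariant), so within
    one chromosome both starts and ends are increasing and candidate partners
    form a contiguous run located with bisection.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b_chrom = b.by_chrom()
    out: dict[str, list[str]] = {}
    for chrom, a_peaks in a.by_chrom().items():
        bp = b_chrom.get(chrom, [])
        starts = [q.start for q in bp]
        ends = [q.end for q in bp]
        for p in a_peaks:
            hits: list[str] = []
            lo = bisect.bisect_right(ends, p.start)
            hi = bisect.bisect_left(starts, p.end, lo=lo)
            for q in bp[lo:hi]:
                if min(p.end, q.end) - max(p.start, q.start) >= min_overlap:
                    hits.append(q.id)
            out[p.id] = hits
    for p in a:
        out.setdefault(p.id, [])
    return out
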