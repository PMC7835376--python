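"""Cross-species coordinate projection and peak conservation labels.

An :class:`OrthologyMap` is a collection of collinear alignment blocks, each
giving the orthologous segment of one locus in two or more species.  Blocks
are modelled as ungapped proportional maps: an offset inside the source
segment maps to ``round(offset / source_len * target_len)`` in the target
segment, with offsets reflected when the block orientations differ.
Peak-level conservation is presence-based: a peak is conserved in another
species when any projected fragment overlaps a peak there by at least
``min_overlap`` bp (1 bp by default); peaks whose projection is empty did
not align and are species-specific.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "AlignmentBlock",
    "OrthologyMap",
    "ConservationLabels",
    "project_interval",
    "classify_conservation",
    "classify_se_conservation",
]

ORIENTATIONS = ("same", "reverse")


@dataclass(frozen=True)
class AlignmentBlock:
    """One orthologous locus: per-species segment plus orientation."""

    block_id: str
    segments: dict  # species -> (GenomicInterval, orientation)

    def __post_init__(self) -> None:
        if len(self.segments) < 2:
            raise ValueError(f"block {self.block_id}: needs >= 2 species")
        for sp, (iv, orient) in self.segments.items():
            if orient not in ORIENTATIONS:
                raise ValueError(
                    f"block {self.block_id}/{sp}: orientation {orient!r}"
                )
            if not isinstance(iv, GenomicInterval):
                raise TypeError("segment must be a GenomicInterval")

    def species(self) -> set[str]:
        return set(self.segments)


class OrthologyMap:
    """Alignment blocks indexed per species by genomic position."""

    def __init__(self, blocks: list[AlignmentBlock]):
        self.blocks = list(blocks)
        # species -> chrom -> (sorted starts, ends, block indices)
        self._index: dict[str, dict[str, tuple[list, list, list]]] = {}
        per: dict[str, dict[str, list[tuple[int, int, int]]]] = {}
        for bi, block in enumerate(self.blocks):
            for sp, (iv, _) in block.segments.items():
                per.setdefault(sp, {}).setdefault(iv.chrom, []).append(
                    (iv.start, iv.end, bi)
                )
        for sp, chroms in per.items():
            self._index[sp] = {}
            for chrom, rows in chroms.items():
                rows.sort()
                starts = [r[0] for r in rows]
                ends = [r[1] for r in rows]
                for i in range(1, len(rows)):
                    if starts[i] < ends[i - 1]:
                        a = self.blocks[rows[i - 1][2]].block_id
                        b = self.blocks[rows[i][2]].block_id
                        raise ValueError(
                            f"{sp}/{chrom}: blocks {a} and {b} overlap"
                        )
                self._index[sp][chrom] = (starts, ends, [r[2] for r in rows])

    def species(self) -> set[str]:
        return set(self._index)

    def blocks_overlapping(self, species: str, iv: GenomicInterval):
        """Blocks whose segment in ``species`` overlaps ``iv``, in order."""
        if species not in self._index:
            raise KeyError(f"species {species!r} not in orthology map")
        idx = self._index[species].get(iv.chrom)
        if idx is None:
            return []
        starts, ends, bids = idx
        lo = bisect.bisect_right(ends, iv.start)
        hi = bisect.bisect_left(starts, iv.end, lo=lo)
        return [self.blocks[bi] for bi in bids[lo:hi]]

    # ---- I/O: tab-separated block table, one row per species-segment ----

    @classmethod
    def read_table(cls, path) -> "OrthologyMap":
        rows: dict[str, dict] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("block_id\t"):
                    continue
                block_id, sp, chrom, start, end, orient = line.split("\t")[:6]
                rows.setdefault(block_id, {})[sp] = (
                    GenomicInterval(chrom, int(start), int(end)),
                    orient,
                )
        blocks = [AlignmentBlock(bid, segs) for bid, segs in rows.items()]
        return cls(blocks)

    def write_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("block_id\tspecies\tchrom\tstart\tend\torientation\n")
            for block in self.blocks:
                for sp in sorted(block.segments):
                    iv, orient = block.segments[sp]
                    fh.write(
                        f"{block.block_id}\t{sp}\t{iv.chrom}\t{iv.start}"
                        f"\t{iv.end}\t{orient}\n"
                    )

    @classmethod
    def identity(cls, species: list[str], chrom_sizes: dict[str, int]) -> "OrthologyMap":
        """One same-orientation block per chromosome with identical
        coordinates in every species; projection through it is the identity."""
        blocks = []
        for chrom, size in chrom_sizes.items():
            segs = {
                sp: (GenomicInterval(chrom, 0, size), "same") for sp in species
            }
            blocks.append(AlignmentBlock(f"ident_{chrom}", segs))
        return cls(blocks)


def _map_offset(off: int, src_len: int, tgt_len: int) -> int:
    return round(off / src_len * tgt_len)


def project_interval(
    iv: GenomicInterval, omap: OrthologyMap, source: str, target: str
) -> list[GenomicInterval]:
    """Project an interval from source-species to target-species coordinates.

    The result may be empty (no alignment) or split across several blocks;
    fragments are clipped to each block and mapped proportionally.
    """
    if source == target:
        raise ValueError("source and target species must differ")
    for sp in (source, target):
        if sp not in omap.species():
            raise KeyError(f"species {sp!r} not in orthology map")
    out: list[GenomicInterval] = []
    for block in omap.blocks_overlapping(source, iv):
        if target not in block.segments:
            continue
        src, src_or = block.segments[source]
        tgt, tgt_or = block.segments[target]
        s = max(iv.start, src.start) - src.start
        e = min(iv.end, src.end) - src.start
        if e <= s:
            continue
        lo = _map_offset(s, src.length, tgt.length)
        hi = _map_offset(e, src.length, tgt.length)
        if hi == lo:  # degenerate after rounding; keep 1 bp
            hi = min(lo + 1, tgt.length)
            lo = hi - 1
        if src_or != tgt_or:  # relative orientation flip reflects offsets
            lo, hi = tgt.length - hi, tgt.length - lo
        out.append(GenomicInterval(tgt.chrom, tgt.start + lo, tgt.start + hi))
    out.sort(key=lambda x: (x.chrom, x.start))
    return out


@dataclass
class ConservationLabels:
    """Per-peak conservation calls from one reference species' perspective."""

    reference: str
    labels: pd.DataFrame = field(repr=False)  # peak_id, n_species, present_in
    partners: dict = field(default_factory=dict, repr=False)
    # partners: peak_id -> {species: [partner peak ids]}

    def present_in(self, peak_id: str) -> set[str]:
        return {sp for sp, ids in self.partners.get(peak_id, {}).items() if ids}

    def conserved_ids(self, min_species: int = 2) -> set[str]:
        df = self.labels
        return set(df.loc[df["n_species"] >= min_species, "peak_id"])

    def category(self, peak_id: str, partner_order: tuple[str, str]) -> str | None:
        """Two-partner conservation category: 'B' (both), 'C' (first partner
        only), 'D' (second only) or None for species-specific peaks."""
        present = {
            sp for sp, ids in self.partners.get(peak_id, {}).items() if ids
        }
        first, second = partner_order
        if first in present and second in present:
            return "B"
        if first in present:
            return "C"
        if second in present:
            return "D"
        return None

    def to_tsv(self, path) -> None:
        df = self.labels.copy()
        df.to_csv(path, sep="\t", index=False)


def _conservation_for_intervals(
    items: list[tuple[str, GenomicInterval]],
    reference: str,
    other_sets: dict[str, object],
    omap: OrthologyMap,
    min_overlap: int,
) -> ConservationLabels:
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    for sp in [reference, *other_sets]:
        if sp not in omap.species():
            raise KeyError(f"species {sp!r} absent from the orthology map")
    # Per-species sorted partner arrays for bisection in target coordinates.
    partner_idx: dict[str, dict[str, tuple[list, list, list]]] = {}
    for sp, pset in other_sets.items():
        per: dict[str, tuple[list, list, list]] = {}
        for chrom, plist in pset.by_chrom().items():
            per[chrom] = (
                [p.start for p in plist],
                [p.end for p in plist],
                [p.id for p in plist],
            )
        partner_idx[sp] = per

    rows = []
    partners: dict[str, dict[str, list[str]]] = {}
    for pid, iv in items:
        hit_by: dict[str, list[str]] = {}
        for sp in other_sets:
            fragments = project_interval(iv, omap, reference, sp)
            hits: list[str] = []
            for frag in fragments:
                idx = partner_idx[sp].get(frag.chrom)
                if idx is None:
                    continue
                starts, ends, ids = idx
                lo = bisect.bisect_right(ends, frag.start)
                hi = bisect.bisect_left(starts, frag.end, lo=lo)
                for j in range(lo, hi):
                    ov = min(frag.end, ends[j]) - max(frag.start, starts[j])
                    if ov >= min_overlap and ids[j] not in hits:
                        hits.append(ids[j])
            hit_by[sp] = hits
        present = sorted(sp for sp, hits in hit_by.items() if hits)
        partners[pid] = hit_by
        rows.append((pid, 1 + len(present), ",".join(present)))
    labels = pd.DataFrame(rows, columns=["peak_id", "n_species", "present_in"])
    return ConservationLabels(reference, labels, partners)


def classify_conservation(
    peaks: PeakSet,
    others: dict[str, PeakSet],
    omap: OrthologyMap,
    min_overlap: int = 1,
) -> ConservationLabels:
    """Label every reference peak by the other species in which an
    orthologous overlapping peak exists (the >= 1 bp rule by default)."""
    items = [(p.id, p.interval) for p in peaks]
    return _conservation_for_intervals(
        items, peaks.species, others, omap, min_overlap
    )


class _IntervalSetView:
    """Adapter giving bare interval lists the tiny PeakSet API needed here."""

    def __init__(self, items: list[tuple[str, GenomicInterval]]):
        self._items = sorted(items, key=lambda t: (t[1].chrom, t[1].start))

    def by_chrom(self):
        out: dict[str, list] = {}
        for pid, iv in self._items:
            out.setdefault(iv.chrom, []).append(_IvProxy(pid, iv))
        return out


class _IvProxy:
    __slots__ = ("id", "start", "end")

    def __init__(self, pid, iv):
        self.id = pid
        self.start = iv.start
        self.end = iv.end


def _as_items(regions, prefix: str) -> list[tuple[str, GenomicInterval]]:
    items = []
    for i, r in enumerate(regions):
        if isinstance(r, tuple):
            items.append(r)
        elif isinstance(r, GenomicInterval):
            items.append((f"{prefix}{i:05d}", r))
        else:  # StitchedRegion-like: has .interval and .region_id
            items.append((r.region_id, r.interval))
    return items


def classify_se_conservation(
    ses,
    other_ses: dict,
    omap: OrthologyMap,
    reference: str,
    min_overlap: int = 1,
) -> ConservationLabels:
    """Conservation labels for stitched super-enhancer intervals: an SE is
    conserved in a species when its projection overlaps an SE there.

    ``ses`` and the values of ``other_ses`` may be lists of
    ``(id, GenomicInterval)`` tuples, bare intervals, or stitched regions.
    """
    items = _as_items(ses, "se_")
    others = {
        sp: _IntervalSetView(_as_items(rs, f"{sp}_se_"))
        for sp, rs in other_ses.items()
    }
    return _conservation_for_intervals(items, reference, others, omap, min_overlap)
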