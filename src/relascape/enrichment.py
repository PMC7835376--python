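"""Fold-enrichment formulas, cell-type sharing, TSS association and variant
overlap.

Every fold enrichment here is a ratio of ratios over a stated universe of
peaks (or super-enhancers).  Writing a = |S & T|, where S is the "special"
set (conserved peaks, SE membership, tissue-shared class, SNP-harbouring
peaks, near-TSS peaks) and T the peak type under test, each printed formula
reduces to

    FE = a * |U| / (|S| * |T|)

so one 2x2 table construction serves them all: rows = in S / not, columns =
in T / not, over the universe U.  The significance test attached to each
formula follows the corresponding figure's convention (chi-squared with
Yates's correction, or two-sided Fisher exact), with Bonferroni adjustment
over the family of types tested together.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pandas as pd

from .intervals import PeakSet, intersect
from .stats import bonferroni, chisq_yates, fisher_two_sided

__all__ = [
    "EnrichmentResult",
    "fold_enrichment",
    "fe_conserved_within_type",
    "fe_within_shared_class",
    "fe_within_se",
    "fe_mode_harboring_se",
    "fe_variant_overlap",
    "assign_to_tss",
    "fe_tss_general",
    "fe_tss_bias_corrected",
    "classify_cell_sharing",
    "sharing_class",
]

_TESTS = {"fisher_two_sided": fisher_two_sided, "chisq_yates": chisq_yates}


@dataclass
class EnrichmentResult:
    label: str
    counts: dict = field(default_factory=dict)  # formula-role name -> count
    fold: float = 0.0
    p_raw: float = 1.0
    p_adj: float = 1.0
    test: str = "fisher_two_sided"
    family_size: int = 1
    undefined: bool = False  # baseline ratio was 0; fold reported as inf

    def as_row(self) -> dict:
        row = {"label": self.label}
        row.update(self.counts)
        row.update(
            fold=self.fold,
            p_raw=self.p_raw,
            p_adj=self.p_adj,
            test=self.test,
            family_size=self.family_size,
        )
        return row


def fold_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Core ratio-of-ratios (a/b)/(c/d); returns (fold, undefined_flag)."""
    if min(a, b, c, d) < 0 or a > b or c > d:
        raise ValueError(f"inconsistent counts a={a} b={b} c={c} d={d}")
    if b == 0 or d == 0:
        raise ValueError("denominator counts b and d must be > 0")
    if c == 0:
        return float("inf"), True
    return (a / b) / (c / d), False


def _from_sets(
    label: str,
    universe: set[str],
    special: set[str],
    type_set: set[str],
    test: str,
    family_size: int,
    count_names: tuple[str, str, str, str],
) -> EnrichmentResult:
    special = special & universe
    type_set = type_set & universe
    n, n_s, n_t = len(universe), len(special), len(type_set)
    n_st = len(special & type_set)
    table = [[n_st, n_s - n_st], [n_t - n_st, n - n_s - n_t + n_st]]
    p_raw = _TESTS[test](table)
    # Both printed ratio orientations equal n_st * n / (n_s * n_t).
    undefined = n_s == 0 or n_t == 0
    fold = float("inf") if undefined else n_st * n / (n_s * n_t)
    counts = dict(zip(count_names, (n_st, n_t, n_s, n)))
    return EnrichmentResult(
        label=label,
        counts=counts,
        fold=fold,
        p_raw=p_raw,
        p_adj=bonferroni(p_raw, family_size),
        test=test,
        family_size=family_size,
        undefined=undefined,
    )


def fe_conserved_within_type(
    conserved_ids: set[str],
    type_ids: set[str],
    all_ids: set[str],
    label: str = "conserved_within_type",
    family_size: int = 1,
) -> EnrichmentResult:
    """(# conserved type-X peaks / # type-X peaks) / (# conserved / # all);
    chi-squared with Yates's correction."""
    return _from_sets(
        label,
        all_ids,
        conserved_ids,
        type_ids,
        "chisq_yates",
        family_size,
        ("conserved_type", "total_type", "total_conserved", "total"),
    )


def fe_within_shared_class(
    class_ids: set[str],
    type_ids: set[str],
    all_ids: set[str],
    label: str = "type_within_shared_class",
    family_size: int = 1,
    test: str = "chisq_yates",
) -> EnrichmentResult:
    """(# class peaks of type X / # class peaks) / (# type X / # all)."""
    return _from_sets(
        label,
        all_ids,
        class_ids,
        type_ids,
        test,
        family_size,
        ("class_type", "total_type", "total_class", "total"),
    )


def fe_within_se(
    se_ids: set[str],
    type_ids: set[str],
    all_ids: set[str],
    label: str = "type_within_se",
    family_size: int = 1,
) -> EnrichmentResult:
    """(# type-X peaks in SEs / # peaks in SEs) / (# type X / # all);
    chi-squared with Yates's correction."""
    return _from_sets(
        label,
        all_ids,
        se_ids,
        type_ids,
        "chisq_yates",
        family_size,
        ("type_in_se", "total_type", "total_in_se", "total"),
    )


def fe_mode_harboring_se(
    class_se_ids: set[str],
    mode_harboring_se_ids: set[str],
    all_se_ids: set[str],
    label: str = "mode_harboring_se_within_class",
    family_size: int = 1,
) -> EnrichmentResult:
    """Enrichment of SEs containing >= 1 mode-X peak within a tissue-shared
    (or -specific) SE class; counted over SEs, not peaks."""
    return _from_sets(
        label,
        all_se_ids,
        class_se_ids,
        mode_harboring_se_ids,
        "chisq_yates",
        family_size,
        ("class_mode_se", "total_mode_se", "total_class_se", "total_se"),
    )


def peaks_with_variants(peaks: PeakSet, variants: pd.DataFrame) -> set[str]:
    """Ids of peaks containing >= 1 variant position (half-open: a variant at
    ``start`` counts, one at ``end`` does not)."""
    per_chrom: dict[str, list[int]] = {}
    for row in variants.itertuples(index=False):
        per_chrom.setdefault(row.chrom, []).append(int(row.pos))
    for positions in per_chrom.values():
        positions.sort()
    hit = set()
    for p in peaks:
        positions = per_chrom.get(p.chrom)
        if not positions:
            continue
        i = bisect.bisect_left(positions, p.start)
        if i < len(positions) and positions[i] < p.end:
            hit.add(p.id)
    return hit


def fe_variant_overlap(
    peaks: PeakSet,
    variants: pd.DataFrame,
    type_ids: set[str],
    label: str = "variant_within_type",
    family_size: int = 1,
) -> EnrichmentResult:
    """(# type-X peaks with SNP / # peaks with SNP) / (# type X / # all);
    chi-squared with Yates's correction."""
    snp_ids = peaks_with_variants(peaks, variants)
    all_ids = set(peaks.ids())
    return _from_sets(
        label,
        all_ids,
        snp_ids,
        type_ids,
        "chisq_yates",
        family_size,
        ("type_with_snp", "total_type", "total_with_snp", "total"),
    )


def assign_to_tss(
    peaks: PeakSet, genes: pd.DataFrame, half_window: int = 10_000
) -> pd.DataFrame:
    """Assign peaks to every gene whose TSS window [tss - w, tss + w)
    overlaps the peak interval; multi-assignment is allowed.

    Returns one row per (peak, gene) assignment with the gene's expression
    class; peaks with no assignment are absent.
    """
    per_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for row in genes.itertuples(index=False):
        per_chrom.setdefault(row.chrom, []).append(
            (int(row.tss), row.gene_id, row.expr_class)
        )
    for rows in per_chrom.values():
        rows.sort()
    out = []
    for p in peaks:
        rows = per_chrom.get(p.chrom)
        if not rows:
            continue
        tss_list = [r[0] for r in rows]
        # overlap of [start, end) with [tss-w, tss+w) <=> tss-w < end and
        # start < tss+w  <=>  start - w < tss < end + w
        lo = bisect.bisect_right(tss_list, p.start - half_window)
        hi = bisect.bisect_left(tss_list, p.end + half_window, lo=lo)
        for tss, gid, cls in rows[lo:hi]:
            if tss - half_window < p.end and p.start < tss + half_window:
                out.append((p.id, gid, cls))
    return pd.DataFrame(out, columns=["peak_id", "gene_id", "expr_class"])


def peaks_near_class(assignments: pd.DataFrame, expr_class: str) -> set[str]:
    return set(
        assignments.loc[assignments["expr_class"] == expr_class, "peak_id"]
    )


def fe_tss_general(
    assignments: pd.DataFrame,
    type_ids: set[str],
    all_ids: set[str],
    expr_class: str,
    label: str | None = None,
    family_size: int = 1,
) -> EnrichmentResult:
    """(# type-X peaks near target-class TSS / # type X) /
    (# peaks near target-class TSS / # all); two-sided Fisher exact."""
    near = peaks_near_class(assignments, expr_class)
    return _from_sets(
        label or f"tss_{expr_class}_within_type",
        all_ids,
        near,
        type_ids,
        "fisher_two_sided",
        family_size,
        ("type_near_tss", "total_type", "total_near_tss", "total"),
    )


def fe_tss_bias_corrected(
    assignments: pd.DataFrame,
    type_ids: set[str],
    expr_class: str,
    label: str | None = None,
    family_size: int = 1,
) -> EnrichmentResult:
    """TSS enrichment computed over peaks near ANY gene, removing the generic
    promoter-proximity bias: (# type-X near target TSS / # type-X near any
    TSS) / (# peaks near target TSS / # peaks near any TSS)."""
    near_any = set(assignments["peak_id"])
    if not (type_ids & near_any):
        raise ValueError("no type peaks near any gene; corrected FE undefined")
    near_target = peaks_near_class(assignments, expr_class)
    return _from_sets(
        label or f"tss_{expr_class}_bias_corrected",
        near_any,
        near_target,
        type_ids,
        "fisher_two_sided",
        family_size,
        ("type_near_target", "total_type_near_any", "total_near_target", "total_near_any"),
    )


def sharing_class(shared_in: set[str], reference: str, ec_types: tuple[str, ...]) -> str:
    """Map the set of cell types sharing a peak to its class label."""
    level = len(shared_in)
    if level >= 4:
        return "pan-cell"
    if level == 3:
        return "3-shared"
    if level == 2:
        if shared_in == set(ec_types):
            return "2-EC-specific"
        return "2-other"
    return "reference-specific"


def classify_cell_sharing(
    ref: PeakSet,
    other_celltypes: dict[str, PeakSet],
    ref_name: str = "HAEC",
    ec_types: tuple[str, ...] = ("HAEC", "HUVEC"),
) -> pd.DataFrame:
    """Label each reference peak by the cell types with an overlapping peak
    (>= 1 bp) and derive the sharing class; the reference cell type is always
    a member.  Columns: peak_id, shared_in, level, class."""
    hit_sets = {
        ct: {pid for pid, hits in intersect(ref, pset).items() if hits}
        for ct, pset in other_celltypes.items()
    }
    rows = []
    for p in ref:
        shared = {ref_name} | {ct for ct, ids in hit_sets.items() if p.id in ids}
        rows.append(
            (p.id, ",".join(sorted(shared)), len(shared), sharing_class(shared, ref_name, ec_types))
        )
    return pd.DataFrame(rows, columns=["peak_id", "shared_in", "level", "class"])
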