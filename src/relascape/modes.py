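"""Chromatin-interaction modes of stimulated RELA peaks and their
cross-species preservation.

A stimulated RELA peak is classified by its overlap with accessible-chromatin
(ATAC) peaks before and after stimulation:

==========  ==========================  =========================
mode        accessible before           accessible after
==========  ==========================  =========================
O  (open)   yes                         yes
OA          no                          yes (opens after)
CA          yes                         no  (closes after)
C  (closed) no                          no
==========  ==========================  =========================

Orthogonally, a peak is *prebound* (Mode P) when it overlaps a RELA peak
called under basal conditions.

Mode preservation asks whether a conserved peak's orthologous partner in
another species carries the same mode.  The expected preservation frequency
under independence is a five-term total-probability sum over the three
conservation categories (conserved in all three species; reference + first
partner only; reference + second partner only), with per-species,
per-category conditional mode probabilities estimated from the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import PeakSet, intersect
from .orthology import ConservationLabels
from .stats import binomial_two_sided, bonferroni

MODES = ("O", "C", "OA", "CA")
MODE_LABELS = ("O", "C", "OA", "CA", "P")  # P = prebound flag as its own label
CATEGORIES = ("B", "C", "D")  # all three / ref+first only / ref+second only

__all__ = [
    "MODES",
    "MODE_LABELS",
    "classify_modes",
    "PreservationModel",
    "fit_preservation_model",
    "preservation_observed",
    "preservation_expected",
    "preservation_test",
    "PreservationResult",
]


def classify_modes(
    rela_stim: PeakSet,
    atac_basal: PeakSet,
    atac_stim: PeakSet,
    rela_basal: PeakSet,
) -> pd.DataFrame:
    """Assign every stimulated RELA peak one mode and a prebound flag.

    All four peak sets must come from the same species.  Overlaps use the
    1 bp rule.  Returns a frame with columns peak_id, mode, prebound.
    """
    species = {rela_stim.species, atac_basal.species, atac_stim.species, rela_basal.species}
    if len(species) != 1:
        raise ValueError(f"peak sets from different species: {sorted(species)}")
    open_pre = {pid for pid, hits in intersect(rela_stim, atac_basal).items() if hits}
    open_post = {pid for pid, hits in intersect(rela_stim, atac_stim).items() if hits}
    prebound = {pid for pid, hits in intersect(rela_stim, rela_basal).items() if hits}
    rows = []
    for p in rela_stim:
        pre, post = p.id in open_pre, p.id in open_post
        if pre and post:
            mode = "O"
        elif post:
            mode = "OA"
        elif pre:
            mode = "CA"
        else:
            mode = "C"
        rows.append((p.id, mode, p.id in prebound))
    return pd.DataFrame(rows, columns=["peak_id", "mode", "prebound"])


def _label_indicator(assign: pd.DataFrame, label: str) -> pd.Series:
    """Boolean indicator for one mode label; 'P' means the prebound flag."""
    if label == "P":
        return assign["prebound"].astype(bool)
    return assign["mode"] == label


@dataclass
class PreservationModel:
    """Category proportions and per-species conditional mode probabilities.

    ``p_category[g]`` is P(g) among conserved reference peaks, and
    ``p_mode[(label, species, g)]`` is P(label | conserved in category g) for
    sites of that species.  ``partner_order`` fixes which partner species
    plays the 'first' (category C) and 'second' (category D) role.
    """

    reference: str
    partner_order: tuple[str, str]
    p_category: dict = field(default_factory=dict)
    p_mode: dict = field(default_factory=dict)
    n_conserved: int = 0

    def __post_init__(self) -> None:
        if self.p_category:
            total = sum(self.p_category.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category proportions sum to {total}, not 1")
        for key, p in self.p_mode.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_mode{key} = {p} outside [0, 1]")


def fit_preservation_model(
    ref_modes: pd.DataFrame,
    partner_modes: dict[str, pd.DataFrame],
    conservation: ConservationLabels,
    partner_order: tuple[str, str],
) -> PreservationModel:
    """Estimate the preservation model from mode assignments and conservation
    labels.

    Partner-species conditional probabilities are computed over the partner
    peaks recorded for each conserved reference peak (a partner site counts
    as carrying a label when any of its overlapping partner peaks does).
    """
    ref_idx = ref_modes.set_index("peak_id")
    partner_idx = {sp: df.set_index("peak_id") for sp, df in partner_modes.items()}

    per_cat_ids: dict[str, list[str]] = {g: [] for g in CATEGORIES}
    for pid in ref_modes["peak_id"]:
        g = conservation.category(pid, partner_order)
        if g is not None:
            per_cat_ids[g].append(pid)
    n_cons = sum(len(v) for v in per_cat_ids.values())
    if n_cons == 0:
        raise ValueError("no conserved peaks; cannot fit a preservation model")
    p_category = {g: len(ids) / n_cons for g, ids in per_cat_ids.items()}

    p_mode: dict[tuple, float] = {}
    for g, ids in per_cat_ids.items():
        species_in_g = [conservation.reference]
        if g in ("B", "C"):
            species_in_g.append(partner_order[0])
        if g in ("B", "D"):
            species_in_g.append(partner_order[1])
        for label in MODE_LABELS:
            for sp in species_in_g:
                if not ids:
                    p_mode[(label, sp, g)] = 0.0
                    continue
                if sp == conservation.reference:
                    sub = ref_idx.loc[ids]
                    frac = float(_label_indicator(sub, label).mean())
                else:
                    hits = 0
                    for pid in ids:
                        pids = conservation.partners[pid].get(sp, [])
                        sub = partner_idx[sp].loc[pids]
                        if bool(_label_indicator(sub, label).any()):
                            hits += 1
                    frac = hits / len(ids)
                p_mode[(label, sp, g)] = frac
    return PreservationModel(
        reference=conservation.reference,
        partner_order=partner_order,
        p_category=p_category,
        p_mode=p_mode,
        n_conserved=n_cons,
    )


def preservation_expected(model: PreservationModel, label: str) -> dict:
    """Five-term expected preservation probability for one mode label.

    Terms: (1) preserved in both partners | conserved in all three;
    (2) preserved in first partner only | all three; (3) second only | all
    three; (4) preserved in first | conserved with first only; (5) preserved
    in second | conserved with second only -- each weighted by its category
    proportion.  Returns the unconditional P(A), the per-term breakdown, and
    the conditional null P(A) / P(label in reference | conserved), which is
    the expected *fraction preserved* among reference label-carrying peaks.
    """
    ref = model.reference
    m1, m2 = model.partner_order
    pB, pC, pD = (model.p_category.get(g, 0.0) for g in CATEGORIES)

    def p(sp, g):
        return model.p_mode.get((label, sp, g), 0.0)

    t1 = p(ref, "B") * p(m1, "B") * p(m2, "B") * pB
    t2 = p(ref, "B") * p(m1, "B") * (1 - p(m2, "B")) * pB
    t3 = p(ref, "B") * (1 - p(m1, "B")) * p(m2, "B") * pB
    t4 = p(ref, "C") * p(m1, "C") * pC
    t5 = p(ref, "D") * p(m2, "D") * pD
    p_a = t1 + t2 + t3 + t4 + t5
    ref_marginal = p(ref, "B") * pB + p(ref, "C") * pC + p(ref, "D") * pD
    conditional = p_a / ref_marginal if ref_marginal > 0 else float("nan")
    return {
        "label": label,
        "terms": (t1, t2, t3, t4, t5),
        "p_a": p_a,
        "ref_marginal": ref_marginal,
        "conditional": conditional,
    }


def preservation_expected_bruteforce(model: PreservationModel, label: str) -> float:
    """Independent oracle for P(A): enumerate all mode-indicator outcomes per
    category instead of using the closed five-term form."""
    ref = model.reference
    m1, m2 = model.partner_order
    total = 0.0
    for g, partners in (("B", (m1, m2)), ("C", (m1,)), ("D", (m2,))):
        pg = model.p_category.get(g, 0.0)
        species = (ref, *partners)
        probs = [model.p_mode.get((label, sp, g), 0.0) for sp in species]
        for outcome in itertools.product((0, 1), repeat=len(species)):
            if not outcome[0]:  # reference must carry the label
                continue
            if not any(outcome[1:]):  # and at least one partner
                continue
            w = 1.0
            for o, pr in zip(outcome, probs):
                w *= pr if o else (1 - pr)
            total += w * pg
    return total


def preservation_observed(
    ref_modes: pd.DataFrame,
    partner_modes: dict[str, pd.DataFrame],
    conservation: ConservationLabels,
    partner_order: tuple[str, str],
) -> pd.DataFrame:
    """Observed per-label preservation counts among conserved reference peaks.

    For each label X: n = conserved reference peaks carrying X, k = those
    whose orthologous partner in at least one other species also carries X.
    Columns ``k_both`` / ``k_first_only`` / ``k_second_only`` split k by
    which partner species preserved the label.
    """
    partner_idx = {sp: df.set_index("peak_id") for sp, df in partner_modes.items()}
    rows = []
    for label in MODE_LABELS:
        ind = _label_indicator(ref_modes, label)
        ids = list(ref_modes.loc[ind, "peak_id"])
        n = k = k_both = k_first = k_second = 0
        for pid in ids:
            cat = conservation.category(pid, partner_order)
            if cat is None:
                continue
            n += 1
            preserved_in = []
            for sp in partner_order:
                pids = conservation.partners[pid].get(sp, [])
                if cat == "C" and sp == partner_order[1]:
                    continue
                if cat == "D" and sp == partner_order[0]:
                    continue
                if pids and cat in ("B", "C", "D"):
                    sub = partner_idx[sp].loc[pids]
                    if bool(_label_indicator(sub, label).any()):
                        preserved_in.append(sp)
                elif not pids and cat == "B":
                    raise RuntimeError(
                        f"conserved peak {pid} has no recorded partner in {sp}"
                    )
            if preserved_in:
                k += 1
                if len(preserved_in) == 2:
                    k_both += 1
                elif preserved_in[0] == partner_order[0]:
                    k_first += 1
                else:
                    k_second += 1
        rows.append((label, k, n, k_both, k_first, k_second))
    return pd.DataFrame(
        rows,
        columns=["label", "k", "n", "k_both", "k_first_only", "k_second_only"],
    )


@dataclass
class PreservationResult:
    """Observed vs expected preservation for one mode label."""

    label: str
    k: int
    n: int
    observed_frac: float
    expected_frac: float
    fold: float
    p_raw: float
    p_adj: float
    degenerate: bool = False


def preservation_test(
    label: str, k: int, n: int, expected_frac: float, n_tests: int = 5
) -> PreservationResult:
    """Two-sided exact binomial test of observed k/n against the expected
    preservation fraction, Bonferroni-adjusted over the label family."""
    if n < 1:
        raise ValueError("need n >= 1 trials")
    if not (0.0 <= expected_frac <= 1.0):
        raise ValueError("expected fraction must be in [0, 1]")
    observed = k / n
    degenerate = expected_frac in (0.0, 1.0) and observed != expected_frac
    if degenerate:
        p_raw = 0.0
    else:
        p_raw = binomial_two_sided(k, n, expected_frac)
    fold = observed / expected_frac if expected_frac > 0 else float("inf")
    return PreservationResult(
        label=label,
        k=k,
        n=n,
        observed_frac=observed,
        expected_frac=expected_frac,
        fold=fold,
        p_raw=p_raw,
        p_adj=bonferroni(p_raw, n_tests),
        degenerate=degenerate,
    )


def preservation_table(
    ref_modes: pd.DataFrame,
    partner_modes: dict[str, pd.DataFrame],
    conservation: ConservationLabels,
    partner_order: tuple[str, str],
) -> pd.DataFrame:
    """Full per-label preservation analysis: observed counts, model-expected
    fractions, folds and Bonferroni-adjusted binomial p-values."""
    model = fit_preservation_model(ref_modes, partner_modes, conservation, partner_order)
    observed = preservation_observed(ref_modes, partner_modes, conservation, partner_order)
    rows = []
    for rec in observed.itertuples(index=False):
        exp = preservation_expected(model, rec.label)
        if rec.n == 0 or not np.isfinite(exp["conditional"]):
            continue
        res = preservation_test(
            rec.label, rec.k, rec.n, exp["conditional"], n_tests=len(MODE_LABELS)
        )
        rows.append(
            (
                rec.label,
                rec.k,
                rec.n,
                res.observed_frac,
                res.expected_frac,
                res.fold,
                res.p_raw,
                res.p_adj,
                exp["p_a"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "k",
            "n",
            "observed_frac",
            "expected_frac",
            "fold",
            "p_raw",
            "p_adj",
            "p_a_unconditional",
        ],
    )
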