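"""Synthetic multi-species peak landscapes with planted ground truth.

The generator emulates the *downstream products* of a cross-species
RELA/ATAC experiment -- peak calls with signals and summits, orthologous
block structure, chromatin modes, super-enhancer neighbourhoods, gene
classes, variant overlaps and motif-bearing sequences -- so that every
pipeline stage can be tested against known truth without any sequencing
data.

Design principles
-----------------
* **Deterministic planting.**  Couplings between labels (which peaks are
  conserved, which prebound peaks sit in super-enhancers, which peaks are
  near upregulated genes, which carry variants) are allocated with exact
  counts rather than Bernoulli draws, so the planted fold enrichments are
  exact numbers, classifier recovery is exact, and the null variant's folds
  are exactly 1 up to integer rounding.
* **Geometry guarantees.**  Inter-locus spacers are longer than both the
  ROSE stitch distance and the TSS window, so stitching and TSS assignment
  cannot leak across loci; intra-cluster gaps are shorter than the stitch
  distance, so planted super-enhancer neighbourhoods stitch into single
  regions.
* **Modes are planted structurally**: accessibility peaks are placed or
  withheld per mode, so the mode classifier recovers planted labels
  exactly.

Default rates follow the reported biology of the TNFa-stimulated
endothelial system: ~30% of reference peaks conserved with at least one
other species (8% in all three), mode proportions O/C/OA/CA =
57/31/9/3, ~1% prebound regions that are a subset of Mode O, a 2x
enrichment of conservation among prebound peaks, 3x prebound enrichment in
super-enhancers and near upregulated-gene TSSs, and a 3x enrichment of
disease variants within three-species-conserved peaks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotations import write_genes_tsv, write_variants_bed
from .intervals import GenomicInterval, Peak, PeakSet, write_narrowpeak
from .motifs import revcomp, write_peak_fasta
from .orthology import AlignmentBlock, OrthologyMap
from .tracks import SignalTrack

__all__ = ["SyntheticConfig", "Landscape", "build_landscape", "generate", "promoter_bias_fixture"]

MODES = ("O", "C", "OA", "CA")
MOTIF_CONSENSUS = "GGGAATTTCC"


def largest_remainder(total: int, props: dict) -> dict:
    """Integer allocation of ``total`` across keys proportional to ``props``,
    exact by the largest-remainder rule (deterministic tie-break by key)."""
    if total == 0:
        return {k: 0 for k in props}
    s = sum(props.values())
    raw = {k: total * v / s for k, v in props.items()}
    out = {k: int(np.floor(r)) for k, r in raw.items()}
    short = total - sum(out.values())
    order = sorted(props, key=lambda k: (-(raw[k] - out[k]), str(k)))
    for k in order[:short]:
        out[k] += 1
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    All fractions are of the reference (human) stimulated RELA peak set
    unless stated otherwise.  Planted folds are the exact fold enrichments
    realised in the emitted counts; setting a fold to 1 removes that
    association (see :meth:`null_variant`).
    """

    species: tuple[str, ...] = ("human", "mouse", "cow")
    n_chromosomes: int = 4
    n_ref_peaks: int = 10_000
    n_partner_specific: int = 3_000

    # conservation structure
    conserved_fraction: float = 0.30
    three_species_fraction: float = 8.0 / 30.0  # of conserved peaks
    unaligned_specific_fraction: float = 0.97  # specific peaks with no block
    reverse_block_fraction: float = 0.10

    # modes and prebound structure
    mode_proportions: tuple[float, ...] = (0.57, 0.31, 0.09, 0.03)  # O,C,OA,CA
    prebound_fraction: float = 0.01
    prebound_conserved_fold: float = 2.0  # FE of conservation within Mode P
    mode_preservation_rate: dict | None = field(
        default_factory=lambda: {"O": 0.65, "C": 0.55, "OA": 0.05, "CA": 0.08, "P": 0.40}
    )

    # geometry (bp)
    peak_width: tuple[int, int] = (340, 600)
    block_margin: int = 400
    spacer_range: tuple[int, int] = (15_000, 40_000)
    summit_jitter: int = 50
    partner_jitter: int = 50

    # super-enhancer neighbourhoods; a None conserved-cluster fraction means
    # mixed clusters with per-peak conservation at the base rate
    se_cluster_count: int = 25
    se_cluster_size: int = 20
    se_conserved_cluster_fraction: float | None = 0.5
    se_intra_gap: tuple[int, int] = (1_000, 3_000)
    prebound_se_fold: float = 3.0

    # signal model
    signal_mu: float = 1.0
    signal_sigma: float = 1.0
    tail_multiplier: float = 20.0  # SE-neighbourhood constituents
    prebound_stim_boost: float = 2.0  # non-SE prebound peaks
    basal_noise_range: tuple[float, float] = (0.1, 1.0)  # bounded basal noise
    prebound_basal_multiplier: float = 50.0  # basal occupancy of prebound peaks

    # genes
    n_up_genes: int = 400
    n_down_genes: int = 160
    n_constitutive_genes: int = 1_000
    near_up_rate: float = 0.04
    near_down_rate: float = 0.012
    near_constitutive_rate: float = 0.05
    prebound_up_fold: float = 3.0
    tss_half_window: int = 10_000

    # variants
    n_variant_peaks: int = 250
    variants_per_peak: int = 2
    variant_conserved_fold: float = 3.0  # within three-species-conserved peaks

    # cell-type sharing
    cell_types: tuple[str, ...] = ("HUVEC", "LCL", "Adipocyte")
    sharing_counts: tuple[int, ...] = (500, 1_000, 1_500, 500)  # pan,3,EC,2-other
    prebound_pancell_fold: float = 17.0
    celltype_specific_peaks: int = 300

    # sequences / motifs
    generate_sequences: bool = True
    gc_content: float = 0.41
    motifs_per_mode: dict = field(
        default_factory=lambda: {"O": 1, "C": 4, "OA": 4, "CA": 1, "P": 4}
    )

    @classmethod
    def for_n_peaks(cls, n: int, **overrides) -> "SyntheticConfig":
        """Defaults with every absolute count scaled to ``n`` reference peaks
        (the stock defaults describe a 10,000-peak landscape)."""
        f = n / 10_000
        scaled = dict(
            n_ref_peaks=n,
            n_partner_specific=max(1, round(3_000 * f)),
            se_cluster_count=max(1, round(25 * f)),
            n_up_genes=max(1, round(400 * f)),
            n_down_genes=max(1, round(160 * f)),
            n_constitutive_genes=max(1, round(1_000 * f)),
            n_variant_peaks=max(1, round(250 * f)),
            sharing_counts=(
                max(1, round(500 * f)), max(1, round(1_000 * f)),
                max(1, round(1_500 * f)), max(1, round(500 * f)),
            ),
            celltype_specific_peaks=max(1, round(300 * f)),
        )
        scaled.update(overrides)
        return cls(**scaled)

    def null_variant(self) -> "SyntheticConfig":
        """Same marginals, all planted associations switched off."""
        return replace(
            self,
            prebound_conserved_fold=1.0,
            prebound_se_fold=1.0,
            prebound_up_fold=1.0,
            variant_conserved_fold=1.0,
            prebound_pancell_fold=1.0,
            mode_preservation_rate=None,
            se_conserved_cluster_fraction=None,
        )


@dataclass
class Landscape:
    """In-memory synthetic landscape plus the planted truth table."""

    config: SyntheticConfig
    seed: int
    peaksets: dict = field(default_factory=dict)  # (species, assay, condition) -> PeakSet
    tracks: dict = field(default_factory=dict)  # name -> SignalTrack
    omap: OrthologyMap | None = None
    genes: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None
    cell_sets: dict = field(default_factory=dict)  # cell type -> PeakSet
    sequences: list = field(default_factory=list)  # write_peak_fasta records
    truth: pd.DataFrame | None = None
    planted: dict = field(default_factory=dict)
    planted_modes: dict = field(default_factory=dict)  # species -> {id: (mode, prebound)}

    def write(self, outdir) -> dict:
        """Write every fixture file; returns a manifest of paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def p(name):
            paths[name] = os.path.join(outdir, name)
            return paths[name]

        for (sp, assay, cond), ps in sorted(self.peaksets.items()):
            write_narrowpeak(ps, p(f"{sp}.{assay.lower()}_{cond}.narrowPeak"))
        for name, track in sorted(self.tracks.items()):
            track.write_bedgraph(p(f"{name}.bedGraph"))
        self.omap.write_table(p("orthology_blocks.tsv"))
        write_genes_tsv(self.genes, p("human.genes.tsv"))
        write_variants_bed(self.variants, p("human.variants.bed"))
        for ct, ps in sorted(self.cell_sets.items()):
            write_narrowpeak(ps, p(f"human.celltype_{ct}.narrowPeak"))
        if self.sequences:
            write_peak_fasta(self.sequences, p("human.peaks.fasta"))
        truth = {
            "schema_version": 1,
            "seed": self.seed,
            "config": _config_json(self.config),
            "planted": self.planted,
            "peaks": self.truth.to_dict(orient="list"),
        }
        with open(p("truth.json"), "w") as fh:
            json.dump(truth, fh, default=_json_scalar)
        return paths


def _json_scalar(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_json(config: SyntheticConfig) -> dict:
    out = dataclasses.asdict(config)
    for k, v in out.items():
        if isinstance(v, tuple):
            out[k] = list(v)
    return out


def _sample_distinct(rng, pool: np.ndarray, k: int, what: str) -> np.ndarray:
    if k > len(pool):
        raise ValueError(
            f"infeasible config: need {k} peaks for {what} but only "
            f"{len(pool)} are available"
        )
    if k == 0:
        return np.empty(0, dtype=pool.dtype)
    return rng.choice(pool, size=k, replace=False)


def build_landscape(config: SyntheticConfig, seed: int) -> Landscape:
    """Construct the full landscape in memory.  Fixed seed => identical
    output, byte for byte once written."""
    rng = np.random.default_rng(seed)
    n = config.n_ref_peaks
    partners = [sp for sp in config.species if sp != config.species[0]]
    if len(partners) != 2:
        raise ValueError("the generator models exactly one reference + two partners")
    ref = config.species[0]
    first, second = partners

    # ---------------- label assignment (reference peaks) ----------------
    idx = np.arange(n)
    n_pre = round(config.prebound_fraction * n)
    pre = np.sort(_sample_distinct(rng, idx, n_pre, "prebound peaks"))
    is_pre = np.zeros(n, dtype=bool)
    is_pre[pre] = True

    n_cons = round(config.conserved_fraction * n)
    cat_props = {
        "B": config.three_species_fraction,
        "C": (1 - config.three_species_fraction) / 2,
        "D": (1 - config.three_species_fraction) / 2,
    }
    cat_counts = largest_remainder(n_cons, cat_props)

    n_pre_cons = min(
        round(config.prebound_conserved_fold * config.conserved_fraction * n_pre),
        n_pre,
    )
    pre_cat_counts = largest_remainder(n_pre_cons, cat_props) if n_cons else {}
    category = np.array(["none"] * n, dtype=object)
    pre_pool = pre.copy()
    for g in ("B", "C", "D"):
        take = _sample_distinct(rng, pre_pool, pre_cat_counts.get(g, 0), f"prebound {g}")
        category[take] = g
        pre_pool = np.setdiff1d(pre_pool, take)
    nonpre = idx[~is_pre]
    nonpre_pool = nonpre.copy()
    for g in ("B", "C", "D"):
        need = cat_counts.get(g, 0) - pre_cat_counts.get(g, 0)
        take = _sample_distinct(rng, nonpre_pool, max(need, 0), f"conserved {g}")
        category[take] = g
        nonpre_pool = np.setdiff1d(nonpre_pool, take)
    is_cons = category != "none"

    # ------------- super-enhancer neighbourhood membership -------------
    n_se = config.se_cluster_count * config.se_cluster_size
    if n_se > 0 and n > 0 and n_pre >= 0:
        f_se = n_se / n
        n_pre_se = min(round(config.prebound_se_fold * f_se * n_pre), n_pre, n_se)
        mixed_clusters = config.se_conserved_cluster_fraction is None
        if mixed_clusters:
            n_cons_clusters = 0
        else:
            n_cons_clusters = round(
                config.se_conserved_cluster_fraction * config.se_cluster_count
            )
        n_cons_se = n_cons_clusters * config.se_cluster_size
        if mixed_clusters:
            # per-peak composition: conservation inside SEs at exactly the
            # base rate, prebound membership at exactly n_pre_se
            pre_se = _sample_distinct(rng, pre, n_pre_se, "prebound SE members")
            n_cons_target = round((n_cons / n) * n_se) if n else 0
            n_cons_rest = max(n_cons_target - int(is_cons[pre_se].sum()), 0)
            cons_rest = _sample_distinct(
                rng, idx[is_cons & ~is_pre], n_cons_rest, "conserved SE members"
            )
            spec_rest = _sample_distinct(
                rng, idx[~is_cons & ~is_pre],
                n_se - n_pre_se - n_cons_rest, "SE members",
            )
            cons_members = np.empty(0, dtype=int)
            spec_se = np.concatenate([pre_se, cons_rest, spec_rest])
            rng.shuffle(spec_se)
        else:
            # prebound SE constituents go to conserved clusters when those
            # exist (preferring three-species-conserved prebound peaks so the
            # partner species inherit full SE neighbourhoods), else to
            # specific clusters
            n_pre_cons_se = min(n_pre_se, n_cons_se)
            pool = idx[is_pre & (category == "B")]
            if len(pool) < n_pre_cons_se:
                pool = idx[is_pre & is_cons]
            n_pre_cons_se = min(n_pre_cons_se, len(pool))
            pre_se_cons = _sample_distinct(
                rng, pool, n_pre_cons_se, "prebound peaks in conserved SEs"
            )
            n_pre_spec_se = n_pre_se - n_pre_cons_se
            pool2 = idx[is_pre & ~is_cons]
            n_pre_spec_se = min(n_pre_spec_se, len(pool2))
            pre_se_spec = _sample_distinct(
                rng, pool2, n_pre_spec_se, "prebound peaks in specific SEs"
            )
            cons_pool = idx[(category == "B") & ~is_pre]
            if len(cons_pool) < n_cons_se - n_pre_cons_se:
                cons_pool = idx[is_cons & ~is_pre]
            cons_se_rest = _sample_distinct(
                rng, cons_pool, n_cons_se - n_pre_cons_se, "conserved SE constituents"
            )
            spec_pool = np.setdiff1d(idx[~is_cons & ~is_pre], pre_se_spec)
            spec_se_rest = _sample_distinct(
                rng, spec_pool, n_se - n_cons_se - n_pre_spec_se,
                "species-specific SE constituents",
            )
            cons_members = np.concatenate([pre_se_cons, cons_se_rest])
            spec_se = np.concatenate([pre_se_spec, spec_se_rest])
            rng.shuffle(cons_members)
            rng.shuffle(spec_se)
    else:
        cons_members = spec_se = np.empty(0, dtype=int)
        n_cons_clusters = 0
        n_pre_se = 0
    se_cluster = np.full(n, -1, dtype=int)
    size = config.se_cluster_size
    for k in range(n_cons_clusters):
        se_cluster[cons_members[k * size : (k + 1) * size]] = k
    for k in range(config.se_cluster_count - n_cons_clusters):
        se_cluster[spec_se[k * size : (k + 1) * size]] = n_cons_clusters + k
    in_se = se_cluster >= 0

    # ------------------------- cell-type sharing -------------------------
    n_pan, n_three, n_ec, n_two = config.sharing_counts
    f_pan = n_pan / n if n else 0.0
    n_pre_pan = min(round(config.prebound_pancell_fold * f_pan * n_pre), n_pre, n_pan)
    pan = np.concatenate(
        [
            _sample_distinct(rng, pre, n_pre_pan, "prebound pan-cell peaks"),
            _sample_distinct(
                rng, nonpre, n_pan - n_pre_pan, "pan-cell peaks"
            ),
        ]
    )
    sharing = np.array(["reference-specific"] * n, dtype=object)
    sharing[pan] = "pan-cell"
    rest = np.setdiff1d(idx, pan)
    three = _sample_distinct(rng, rest, n_three, "3-shared peaks")
    sharing[three] = "3-shared"
    rest = np.setdiff1d(rest, three)
    ec = _sample_distinct(rng, rest, n_ec, "EC-specific peaks")
    sharing[ec] = "2-EC-specific"
    rest = np.setdiff1d(rest, ec)
    two = _sample_distinct(rng, rest, n_two, "2-other peaks")
    sharing[two] = "2-other"

    # ------------------------------ modes ------------------------------
    # Exact global mode counts, distributed hierarchically (SE / non-SE,
    # then conserved / specific) so every stratum carries the global mode
    # mix up to a single count; capacity mismatches from rounding are
    # absorbed by the large Mode-O pool.  Prebound peaks are Mode O.
    mode = np.array([""] * n, dtype=object)
    mode[is_pre] = "O"
    mode_targets = dict(zip(MODES, config.mode_proportions))
    global_counts = largest_remainder(n, mode_targets)
    if global_counts["O"] < n_pre:
        raise ValueError(
            "infeasible config: more prebound peaks than Mode O peaks"
        )
    totals = dict(global_counts)
    totals["O"] -= n_pre  # remaining O to distribute among non-prebound peaks

    def _split_modes(groups: dict, totals_in: dict) -> dict:
        """Split per-mode totals across groups proportional to group size,
        exactly; per-group capacity repaired through Mode O."""
        sizes = {k: len(v) for k, v in groups.items()}
        out = {k: dict.fromkeys(MODES, 0) for k in groups}
        for m in MODES:
            alloc = largest_remainder(totals_in[m], {k: max(s, 1e-9) for k, s in sizes.items()})
            for k in groups:
                out[k][m] = alloc[k]
        for k in groups:
            out[k]["O"] += sizes[k] - sum(out[k].values())
            if out[k]["O"] < 0:
                raise ValueError("infeasible mode allocation (Mode O underflow)")
        return out

    level1 = {
        "se": idx[in_se & ~is_pre],
        "nonse": idx[~in_se & ~is_pre],
    }
    alloc1 = _split_modes(level1, totals)
    for key, members in level1.items():
        sub = {
            "cons": members[is_cons[members]],
            "spec": members[~is_cons[members]],
        }
        alloc2 = _split_modes(sub, alloc1[key])
        for k2, mem in sub.items():
            mem = rng.permutation(mem)
            pos = 0
            for m in MODES:
                mode[mem[pos : pos + alloc2[k2][m]]] = m
                pos += alloc2[k2][m]

    # ------------------------ near-TSS structure ------------------------
    n_near_up = round(config.near_up_rate * n)
    n_pre_up = min(
        round(config.prebound_up_fold * config.near_up_rate * n_pre),
        n_pre,
        n_near_up,
    )
    pre_non_se = np.setdiff1d(pre, idx[in_se])
    non_se_nonpre = idx[~in_se & ~is_pre]
    near_up = np.concatenate(
        [
            _sample_distinct(rng, pre_non_se, n_pre_up, "prebound near-up peaks"),
            _sample_distinct(
                rng, non_se_nonpre, n_near_up - n_pre_up, "near-up peaks"
            ),
        ]
    )
    non_se = idx[~in_se]
    near_down = _sample_distinct(
        rng, non_se, round(config.near_down_rate * n), "near-down peaks"
    )
    near_const = _sample_distinct(
        rng, non_se, round(config.near_constitutive_rate * n), "near-constitutive peaks"
    )
    is_near_up = np.zeros(n, dtype=bool)
    is_near_up[near_up] = True

    # ------------------------------ variants ------------------------------
    n_var = min(config.n_variant_peaks, n)
    b_all = idx[category == "B"]
    frac_b = len(b_all) / n if n else 0.0
    n_var_b = min(round(config.variant_conserved_fold * frac_b * n_var), n_var, len(b_all))
    var_peaks = np.concatenate(
        [
            _sample_distinct(rng, b_all, n_var_b, "variant-bearing conserved peaks"),
            _sample_distinct(
                rng, np.setdiff1d(idx, b_all), n_var - n_var_b, "variant-bearing peaks"
            ),
        ]
    )
    has_variant = np.zeros(n, dtype=bool)
    has_variant[var_peaks] = True

    # ------------------------------ signals ------------------------------
    # the heavy tail IS the SE neighbourhoods; prebound peaks get a separate
    # (smaller) boost so individual prebound regions stay below stitched
    # cluster aggregates while still being the most induced single peaks
    stim_signal = np.exp(rng.normal(config.signal_mu, config.signal_sigma, size=n))
    stim_signal[in_se] *= config.tail_multiplier
    stim_signal[is_pre & ~in_se] *= config.prebound_stim_boost
    # bounded basal noise keeps the sorted basal curve dense at its top, so
    # the inflection cutoff pins at the gap below the prebound population
    basal_signal = rng.uniform(*config.basal_noise_range, size=n)
    basal_signal[is_pre] *= config.prebound_basal_multiplier

    # -------------------- partner modes (preservation) --------------------
    rates = config.mode_preservation_rate
    mode_p = np.asarray(config.mode_proportions)

    def draw_partner_mode(ref_mode: str) -> str:
        if rates is None:
            return rng.choice(MODES, p=mode_p)
        r = rates[ref_mode] if isinstance(rates, dict) else rates
        if rng.random() < r:
            return ref_mode
        others = [m for m in MODES if m != ref_mode]
        w = np.array([mode_targets[m] for m in others])
        return rng.choice(others, p=w / w.sum())

    def draw_partner_prebound(ref_pre: bool, partner_mode: str) -> bool:
        if rates is None:
            return partner_mode == "O" and rng.random() < config.prebound_fraction
        r = rates["P"] if isinstance(rates, dict) else rates
        return ref_pre and rng.random() < r

    partner_mode: dict[str, list] = {first: [None] * n, second: [None] * n}
    partner_pre: dict[str, list] = {first: [False] * n, second: [False] * n}
    for i in range(n):
        targets = []
        if category[i] == "B":
            targets = [first, second]
        elif category[i] == "C":
            targets = [first]
        elif category[i] == "D":
            targets = [second]
        for sp in targets:
            m = draw_partner_mode(mode[i])
            pre_flag = draw_partner_prebound(bool(is_pre[i]), m)
            if pre_flag:
                m = "O"
            partner_mode[sp][i] = m
            partner_pre[sp][i] = pre_flag

    # ------------------------------ layout ------------------------------
    layout = _layout(
        config,
        rng,
        ref,
        first,
        second,
        dict(
            mode=mode,
            is_pre=is_pre,
            category=category,
            se_cluster=se_cluster,
            stim_signal=stim_signal,
            basal_signal=basal_signal,
            partner_mode=partner_mode,
            partner_pre=partner_pre,
            near_up=near_up,
            near_down=near_down,
            near_const=near_const,
            var_peaks=var_peaks,
        ),
    )

    truth = pd.DataFrame(
        {
            "peak_id": layout["ref_ids"],
            "mode": mode,
            "prebound": is_pre,
            "category": category,
            "partner_first": layout["partner_of"][first],
            "partner_second": layout["partner_of"][second],
            "se_cluster": se_cluster,
            "se_member": in_se,
            "se_cluster_conserved": (se_cluster >= 0) & (se_cluster < n_cons_clusters),
            "sharing": sharing,
            "near_up": is_near_up,
            "has_variant": has_variant,
            "stim_signal": stim_signal,
            "basal_signal": basal_signal,
        }
    )

    planted = {
        "conserved_fraction": n_cons / n if n else 0.0,
        "three_species_fraction_of_all": cat_counts.get("B", 0) / n if n else 0.0,
        "mode_counts": {m: int((mode == m).sum()) for m in MODES},
        "n_prebound": int(n_pre),
        "prebound_conserved_fold": (
            (n_pre_cons / n_pre) / (n_cons / n) if n_pre and n_cons else float("nan")
        ),
        "prebound_se_fold": (
            (n_pre_se / n_se) / (n_pre / n) if n_se and n_pre else float("nan")
        ),
        "prebound_up_fold": (
            (n_pre_up / n_pre) / (n_near_up / n) if n_pre and n_near_up else float("nan")
        ),
        "variant_conserved_fold": (
            (n_var_b / n_var) / (len(b_all) / n) if n_var and len(b_all) else float("nan")
        ),
        "prebound_pancell_fold": (
            (n_pre_pan / n_pre) / (n_pan / n) if n_pre and n_pan else float("nan")
        ),
        "n_se_clusters": config.se_cluster_count,
        "n_conserved_se_clusters": int(n_cons_clusters),
    }

    land = Landscape(
        config=config,
        seed=seed,
        peaksets=layout["peaksets"],
        tracks=layout["tracks"],
        omap=layout["omap"],
        genes=layout["genes"],
        variants=layout["variants"],
        cell_sets=_cell_sets(config, rng, layout, sharing),
        truth=truth,
        planted=planted,
        planted_modes=layout["spec_modes"],
    )
    if config.generate_sequences:
        land.sequences = _sequences(config, rng, layout, mode, is_pre)
    return land


# ---------------------------------------------------------------------------
# genomic layout
# ---------------------------------------------------------------------------


def _layout(config, rng, ref, first, second, labels):
    """Place every locus on chromosomes, species by species, and build peak
    sets, alignment blocks, tracks, genes and variants."""
    n = config.n_ref_peaks
    mode = labels["mode"]
    category = labels["category"]
    se_cluster = labels["se_cluster"]
    margin = config.block_margin

    # units: SE clusters keep their constituents adjacent; everything else
    # is a single-locus unit.  Partner-specific peaks and gene deserts are
    # their own units.
    cluster_units: dict[int, list[int]] = {}
    singles = []
    for i in range(n):
        if se_cluster[i] >= 0:
            cluster_units.setdefault(int(se_cluster[i]), []).append(i)
        else:
            singles.append(i)
    units: list[tuple] = [("cluster", members) for members in cluster_units.values()]
    units += [("ref", i) for i in singles]
    units += [("partner_specific", sp, j) for sp in (first, second)
              for j in range(config.n_partner_specific)]
    n_far_genes = (
        config.n_down_genes - len(labels["near_down"])
        + config.n_constitutive_genes - len(labels["near_const"])
        + max(config.n_up_genes - len(labels["near_up"]), 0)
    )
    units += [("desert", j) for j in range(max(n_far_genes, 0))]
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    cursors = {sp: {} for sp in (ref, first, second)}  # species -> chrom -> pos
    per_chrom = -(-len(units) // config.n_chromosomes)

    state = {
        "blocks": [],
        "peaks": {sp: [] for sp in (ref, first, second)},  # stim RELA peaks
        "ref_ids": [None] * n,
        "partner_of": {first: [""] * n, second: [""] * n},
        "ref_coords": [None] * n,  # (chrom, start, end, summit)
        "desert_tss": [],
        "counter": {sp: 0 for sp in (ref, first, second)},
        "bg_positions": {sp: [] for sp in (ref, first, second)},
    }

    def advance(sp, chrom, dist):
        cursors[sp][chrom] = cursors[sp].get(chrom, 0) + dist
        return cursors[sp][chrom]

    def place_ref_locus(i, chrom, spacer_for):
        """One reference peak, its block (if conserved) and partner peaks.

        ``spacer_for(sp)`` gives each species its own gap before this locus:
        a species entering a cluster late must still clear the full spacer
        from its previous placement.
        """
        width = int(rng.integers(*config.peak_width))
        block_len = width + 2 * margin
        targets = {"B": [first, second], "C": [first], "D": [second]}.get(
            str(category[i]), []
        )
        aligned_species = [ref] + targets
        if not targets and rng.random() > config.unaligned_specific_fraction:
            # aligned-but-empty locus: projects, but finds no partner peak
            aligned_species = [ref, first]
        segments = {}
        start = advance(ref, chrom, spacer_for(ref)) ; advance(ref, chrom, block_len)
        pstart = start + margin
        summit = pstart + width // 2 + int(
            rng.integers(-config.summit_jitter, config.summit_jitter + 1)
        )
        pid = f"h{state['counter'][ref]:06d}"
        state["counter"][ref] += 1
        state["peaks"][ref].append(
            (pid, chrom, pstart, pstart + width, summit,
             labels["stim_signal"][i], i)
        )
        state["ref_ids"][i] = pid
        state["ref_coords"][i] = (chrom, pstart, pstart + width, summit)
        if len(aligned_species) > 1:
            segments[ref] = (GenomicInterval(chrom, start, start + block_len), "same")
        for sp in aligned_species[1:]:
            orient = "reverse" if rng.random() < config.reverse_block_fraction else "same"
            s2 = advance(sp, chrom, spacer_for(sp)) ; advance(sp, chrom, block_len)
            segments[sp] = (GenomicInterval(chrom, s2, s2 + block_len), orient)
            if sp in targets:
                off = margin
                if orient == "reverse":
                    off = block_len - margin - width
                jit = int(rng.integers(-config.partner_jitter, config.partner_jitter + 1))
                q_start = s2 + min(max(off + jit, 0), block_len - width)
                q_summit = q_start + width // 2
                prefix = "m" if sp == first else "c"
                qid = f"{prefix}{state['counter'][sp]:06d}"
                state["counter"][sp] += 1
                sig = np.exp(rng.normal(config.signal_mu, config.signal_sigma))
                if se_cluster[i] >= 0:
                    sig *= config.tail_multiplier
                elif labels["partner_pre"][sp][i]:
                    sig *= config.prebound_stim_boost
                state["peaks"][sp].append(
                    (qid, chrom, q_start, q_start + width, q_summit, sig, i)
                )
                state["partner_of"][sp][i] = qid
        if segments:
            state["blocks"].append(
                AlignmentBlock(f"blk{len(state['blocks']):06d}", segments)
            )

    unit_no = 0
    for u, unit in enumerate(units):
        chrom = f"chr{u // per_chrom + 1}"
        kind = unit[0]
        if kind == "cluster":
            members = unit[1]
            placed_in_cluster: set = set()

            def cluster_spacer(sp):
                if sp in placed_in_cluster:
                    return int(rng.integers(*config.se_intra_gap))
                placed_in_cluster.add(sp)
                return int(rng.integers(*config.spacer_range))

            for i in members:
                place_ref_locus(i, chrom, cluster_spacer)
        elif kind == "ref":
            i = unit[1]
            spacer = int(rng.integers(*config.spacer_range))
            place_ref_locus(i, chrom, lambda sp: spacer)
            if unit_no % 10 == 0:  # background accessible region in the next
                # spacer; +7000 stays clear of both neighbours (spacers are
                # >= 15000, ATAC/cell-type widths <= 400)
                for sp in (ref, first, second):
                    pos = cursors[sp].get(chrom, 0)
                    loc = (chrom, pos + 7_000)
                    if loc not in state["bg_positions"][sp]:
                        state["bg_positions"][sp].append(loc)
            unit_no += 1
        elif kind == "partner_specific":
            sp = unit[1]
            spacer = int(rng.integers(*config.spacer_range))
            width = int(rng.integers(*config.peak_width))
            s2 = advance(sp, chrom, spacer) ; advance(sp, chrom, width + 2 * margin)
            pstart = s2 + margin
            prefix = "m" if sp == first else "c"
            qid = f"{prefix}{state['counter'][sp]:06d}"
            state["counter"][sp] += 1
            sig = np.exp(rng.normal(config.signal_mu, config.signal_sigma))
            state["peaks"][sp].append(
                (qid, chrom, pstart, pstart + width, pstart + width // 2, sig, -1)
            )
        elif kind == "desert":
            length = 2 * config.tss_half_window + 5_000
            s2 = advance(ref, chrom, int(rng.integers(*config.spacer_range)))
            advance(ref, chrom, length)
            state["desert_tss"].append((chrom, s2 + length // 2))

    # ---- assemble peak sets, ATAC sets, tracks, map, genes, variants ----
    peaksets = {}
    tracks = {}
    spec_modes = {}  # species -> {peak_id: (mode, prebound)}
    for sp in (ref, first, second):
        recs = state["peaks"][sp]
        peaks = [
            Peak(GenomicInterval(c, s, e), pid, float(sig), su)
            for pid, c, s, e, su, sig, _ in recs
        ]
        peaksets[(sp, "RELA", "stimulated")] = PeakSet(sp, "RELA", "stimulated", peaks)
        modes_sp = {}
        for pid, c, s, e, su, sig, i in recs:
            if sp == ref:
                modes_sp[pid] = (str(mode[i]), bool(labels["is_pre"][i]))
            elif i >= 0:
                modes_sp[pid] = (
                    str(labels["partner_mode"][sp][i]),
                    bool(labels["partner_pre"][sp][i]),
                )
            else:
                m = rng.choice(MODES, p=np.asarray(config.mode_proportions))
                modes_sp[pid] = (str(m), False)
        spec_modes[sp] = modes_sp

        atac_basal, atac_stim, rela_basal = [], [], []
        for pid, c, s, e, su, sig, i in recs:
            m, pre_flag = modes_sp[pid]
            half = 150
            iv = GenomicInterval(c, su - half, su + half)
            if m in ("O", "CA"):
                atac_basal.append((iv, f"ab_{pid}"))
            if m in ("O", "OA"):
                atac_stim.append((iv, f"as_{pid}"))
            if pre_flag:
                if sp == ref:
                    bsig = labels["basal_signal"][i]
                else:
                    bsig = config.prebound_basal_multiplier * rng.uniform(
                        *config.basal_noise_range
                    )
                rela_basal.append(
                    Peak(GenomicInterval(c, s, e), f"b_{pid}", float(bsig), su)
                )
        for chrom, pos in state["bg_positions"][sp]:
            iv = GenomicInterval(chrom, pos, pos + 300)
            atac_basal.append((iv, f"abg_{sp}_{pos}_{chrom}"))
            atac_stim.append((iv, f"asg_{sp}_{pos}_{chrom}"))
        peaksets[(sp, "ATAC", "basal")] = PeakSet(
            sp, "ATAC", "basal",
            [Peak(iv, pid, 1.0, (iv.start + iv.end) // 2) for iv, pid in atac_basal],
        )
        peaksets[(sp, "ATAC", "stimulated")] = PeakSet(
            sp, "ATAC", "stimulated",
            [Peak(iv, pid, 1.0, (iv.start + iv.end) // 2) for iv, pid in atac_stim],
        )
        peaksets[(sp, "RELA", "basal")] = PeakSet(sp, "RELA", "basal", rela_basal)

    # tracks (reference species): bedGraph steps that integrate over each
    # peak to exactly that peak's recorded signal
    stim_steps, basal_steps, constraint_steps = [], [], []
    for pid, c, s, e, su, sig, i in state["peaks"][ref]:
        w = e - s
        stim_steps.append((c, s, e, sig / w))
        basal_steps.append((c, s, e, labels["basal_signal"][i] / w))
        gerp = rng.normal(3.0, 0.2) if category[i] != "none" else rng.normal(1.0, 0.2)
        constraint_steps.append((c, s, e, float(gerp)))
    tracks[f"{ref}.rela_stimulated"] = SignalTrack.from_intervals(stim_steps, "RPM")
    tracks[f"{ref}.rela_basal"] = SignalTrack.from_intervals(basal_steps, "RPM")
    tracks[f"{ref}.constraint"] = SignalTrack.from_intervals(
        constraint_steps, "constraint"
    )

    # anchor block: the alignment covers every species even if no peak locus
    # does (placed well past all loci, so it never carries a peak)
    anchor_pos = 50_000 + max(
        (pos for cur in cursors.values() for pos in cur.values()), default=0
    )
    state["blocks"].append(
        AlignmentBlock(
            "blk_anchor",
            {
                sp: (GenomicInterval("chr1", anchor_pos, anchor_pos + 1_000), "same")
                for sp in (ref, first, second)
            },
        )
    )
    omap = OrthologyMap(state["blocks"])

    # genes: "near" genes get their TSS inside the chosen peak; far genes
    # live in dedicated deserts with >= 10 kb clearance on each side
    gene_rows = []
    deserts = list(state["desert_tss"])

    def add_genes(prefix, cls, near_peaks, total):
        for k, i in enumerate(near_peaks):
            chrom, s, e, _ = state["ref_coords"][i]
            tss = int(rng.integers(s, e))
            gene_rows.append((f"{prefix}{k:05d}", chrom, tss, "+", cls))
        for k in range(total - len(near_peaks)):
            chrom, tss = deserts.pop()
            gene_rows.append((f"{prefix}{len(near_peaks) + k:05d}", chrom, tss, "+", cls))

    add_genes("gu", "up", labels["near_up"], config.n_up_genes)
    add_genes("gd", "down", labels["near_down"], config.n_down_genes)
    add_genes("gc", "constitutive", labels["near_const"], config.n_constitutive_genes)
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss", "strand", "expr_class"]
    )

    variant_rows = []
    for i in labels["var_peaks"]:
        chrom, s, e, _ = state["ref_coords"][i]
        for j in range(config.variants_per_peak):
            pos = int(rng.integers(s, e))
            variant_rows.append((chrom, pos, f"v_{state['ref_ids'][i]}_{j}"))
    variants = pd.DataFrame(variant_rows, columns=["chrom", "pos", "id"])

    return dict(
        peaksets=peaksets,
        tracks=tracks,
        omap=omap,
        genes=genes,
        variants=variants,
        ref_ids=state["ref_ids"],
        partner_of=state["partner_of"],
        ref_coords=state["ref_coords"],
        spec_modes=spec_modes,
        bg_positions=state["bg_positions"],
        ref=ref,
    )


def _cell_sets(config, rng, layout, sharing):
    """Per-cell-type peak sets realising the planted sharing classes."""
    ref_coords = layout["ref_coords"]
    others = list(config.cell_types)
    membership: dict[str, list] = {ct: [] for ct in others}
    for i, cls in enumerate(sharing):
        if cls == "pan-cell":
            present = others
        elif cls == "3-shared":
            present = list(rng.choice(others, size=2, replace=False))
        elif cls == "2-EC-specific":
            present = [others[0]]  # HUVEC: the other endothelial cell type
        elif cls == "2-other":
            present = [others[1 + int(rng.integers(0, len(others) - 1))]]
        else:
            present = []
        for ct in present:
            membership[ct].append(i)
    sets = {}
    for ct in others:
        peaks = []
        for i in membership[ct]:
            chrom, s, e, su = ref_coords[i]
            ds = int(rng.integers(0, 50))
            de = int(rng.integers(0, 50))
            peaks.append(
                Peak(GenomicInterval(chrom, s + ds, e - de), f"{ct}_{i:06d}", 1.0, su)
            )
        for k, (chrom, pos) in enumerate(layout["bg_positions"][layout["ref"]]):
            if k % len(others) == others.index(ct):
                shift = 5_000
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, pos + shift, pos + shift + 400),
                        f"{ct}_own_{k:05d}", 1.0, pos + shift + 200,
                    )
                )
        sets[ct] = PeakSet(ct, "RELA", "stimulated", peaks)
    return sets


def _sequences(config, rng, layout, mode, is_pre):
    """Peak sequences with planted consensus motifs near the summit."""
    bases = np.array(list("ACGT"))
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    W = len(MOTIF_CONSENSUS)
    records = []
    for i, pid in enumerate(layout["ref_ids"]):
        chrom, s, e, su = layout["ref_coords"][i]
        L = e - s
        seq = rng.choice(bases, size=L, p=probs)
        label = "P" if is_pre[i] else str(mode[i])
        m = int(config.motifs_per_mode.get(label, 0))
        so = su - s
        slot_starts = np.arange(max(so - 100, 0), min(so + 100, L - W) + 1, 2 * W)
        if m > 0 and len(slot_starts) > 0:
            chosen = rng.choice(slot_starts, size=min(m, len(slot_starts)), replace=False)
            for pos in chosen:
                word = MOTIF_CONSENSUS if rng.random() < 0.5 else revcomp(MOTIF_CONSENSUS)
                seq[pos : pos + W] = list(word)
        records.append((pid, chrom, s, e, su, "".join(seq)))
    return records


def generate(config: SyntheticConfig, seed: int, outdir) -> Landscape:
    """Build a landscape and write the full fixture directory."""
    land = build_landscape(config, seed)
    land.write(outdir)
    return land


# ---------------------------------------------------------------------------
# promoter-bias construction
# ---------------------------------------------------------------------------


def promoter_bias_fixture(
    seed: int,
    n_peaks: int = 2_000,
    conserved_fraction: float = 0.3,
    near_rate_conserved: float = 0.9,
    near_rate_other: float = 0.2,
    class_props: dict | None = None,
):
    """Landscape where conserved peaks concentrate near gene TSSs but gene
    *classes* are assigned independently of conservation.

    The general TSS formula then reports an inflated fold for every class
    (conserved peaks are simply closer to genes), while the bias-corrected
    formula -- computed over peaks near any gene -- returns 1.  Gene classes
    are allocated with exact counts so the corrected fold is exactly 1 up to
    integer rounding.  Returns (PeakSet, genes frame, conserved id set).
    """
    rng = np.random.default_rng(seed)
    class_props = class_props or {"up": 0.3, "down": 0.2, "constitutive": 0.5}
    n_cons = round(conserved_fraction * n_peaks)
    peaks, rows = [], []
    conserved_ids = set()
    spacing = 25_000
    n_near_cons = round(near_rate_conserved * n_cons)
    n_near_other = round(near_rate_other * (n_peaks - n_cons))
    near_flags = (
        [True] * n_near_cons + [False] * (n_cons - n_near_cons),
        [True] * n_near_other + [False] * (n_peaks - n_cons - n_near_other),
    )
    for flags in near_flags:
        rng.shuffle(flags)
    gene_classes = []
    for n_near in (n_near_cons, n_near_other):
        alloc = largest_remainder(n_near, class_props)
        cls = [c for c, k in alloc.items() for _ in range(k)]
        rng.shuffle(cls)
        gene_classes.append(cls)
    g = 0
    for i in range(n_peaks):
        start = (i + 1) * spacing
        width = 500
        conserved = i < n_cons
        pid = f"pb{i:05d}"
        if conserved:
            conserved_ids.add(pid)
        peaks.append(
            Peak(GenomicInterval("chr1", start, start + width), pid, 1.0, start + 250)
        )
        pool = 0 if conserved else 1
        j = i if conserved else i - n_cons
        if near_flags[pool][j]:
            cls = gene_classes[pool].pop()
            tss = int(rng.integers(start, start + width))
            rows.append((f"g{g:05d}", "chr1", tss, "+", cls))
            g += 1
    peakset = PeakSet("human", "RELA", "stimulated", peaks)
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "expr_class"])
    return peakset, genes, conserved_ids
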