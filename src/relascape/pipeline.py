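"""End-to-end orchestration of the comparative analysis.

Stages run in dependency order: conservation calling, mode classification,
mode preservation, super-enhancer and top-ranked peak calling, motif
scanning, and the enrichment battery.  Every stage writes a self-describing
TSV into the output directory; a manifest records parameters and input
checksums so a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .annotations import read_genes_tsv, read_variants
from .enrichment import (
    classify_cell_sharing,
    fe_conserved_within_type,
    fe_tss_bias_corrected,
    fe_tss_general,
    fe_variant_overlap,
    fe_within_se,
    fe_within_shared_class,
    assign_to_tss,
)
from .intervals import PeakSet, read_narrowpeak
from .modes import MODE_LABELS, _label_indicator, classify_modes, preservation_table
from .motifs import (
    estimate_background,
    motif_density_profile,
    motifs_per_peak,
    read_jaspar_pfm,
    read_peak_fasta,
    scan_peaks,
)
from .orthology import OrthologyMap, classify_conservation, classify_se_conservation
from .stats import bonferroni, mann_whitney_two_sided
from .superenhancers import call_superenhancers, top_ranked_peaks
from .tracks import SignalTrack

STAGES = ("conserve", "modes", "preserve", "se", "toprank", "motifs", "enrich")

DEFAULT_PARAMETERS = dict(
    min_overlap=1,
    overlap_grid=(1, 20, 50, 100),
    stitch_distance=12_500,
    tss_half_window=10_000,
    motif_threshold=1.0,
    motif_half_window=100,
    background_order=1,
)


@dataclass
class PipelineConfig:
    reference: str
    partners: tuple[str, str]
    inputs: dict  # species -> {rela_stimulated, rela_basal, atac_basal, atac_stimulated}
    orthology_map: str
    tracks: dict = field(default_factory=dict)  # rela_basal / rela_stimulated / constraint
    genes: str | None = None
    variants: str | None = None
    peak_fasta: str | None = None
    pwm: str | None = None
    cell_types: dict = field(default_factory=dict)  # cell type -> peak path
    parameters: dict = field(default_factory=dict)
    output_dir: str = "relascape_out"

    def __post_init__(self) -> None:
        params = dict(DEFAULT_PARAMETERS)
        params.update(self.parameters)
        self.parameters = params
        for sp in (self.reference, *self.partners):
            if sp not in self.inputs:
                raise ValueError(f"no input files configured for species {sp!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["partners"] = tuple(raw["partners"])
        return cls(**raw)

    def input_files(self) -> list[str]:
        files = [self.orthology_map]
        for sp_files in self.inputs.values():
            files.extend(sp_files.values())
        files.extend(self.tracks.values())
        files.extend(self.cell_types.values())
        for f in (self.genes, self.variants, self.peak_fasta, self.pwm):
            if f:
                files.append(f)
        return files

    @classmethod
    def for_fixture_dir(cls, fixture_dir, output_dir) -> "PipelineConfig":
        """Configuration over the file layout written by the synthetic-data
        generator."""
        d = str(fixture_dir)

        def p(name):
            return os.path.join(d, name)

        species = ("human", "mouse", "cow")
        inputs = {
            sp: dict(
                rela_stimulated=p(f"{sp}.rela_stimulated.narrowPeak"),
                rela_basal=p(f"{sp}.rela_basal.narrowPeak"),
                atac_basal=p(f"{sp}.atac_basal.narrowPeak"),
                atac_stimulated=p(f"{sp}.atac_stimulated.narrowPeak"),
            )
            for sp in species
        }
        cell_types = {
            ct: p(f"human.celltype_{ct}.narrowPeak")
            for ct in ("HUVEC", "LCL", "Adipocyte")
            if os.path.exists(p(f"human.celltype_{ct}.narrowPeak"))
        }
        fasta = p("human.peaks.fasta")
        return cls(
            reference="human",
            partners=("mouse", "cow"),
            inputs=inputs,
            orthology_map=p("orthology_blocks.tsv"),
            tracks=dict(
                rela_basal=p("human.rela_basal.bedGraph"),
                rela_stimulated=p("human.rela_stimulated.bedGraph"),
                constraint=p("human.constraint.bedGraph"),
            ),
            genes=p("human.genes.tsv"),
            variants=p("human.variants.bed"),
            peak_fasta=fasta if os.path.exists(fasta) else None,
            cell_types=cell_types,
            output_dir=str(output_dir),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_pwm_path() -> str:
    import importlib.resources as ir

    import relascape

    return str(ir.files(relascape) / "data" / "rela_pwm_synthetic.jaspar")


class PipelineRun:
    """Loads inputs lazily and executes stages in dependency order."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.results: dict = {}
        self._loaded = False

    # ------------------------------ loading ------------------------------

    def load(self) -> None:
        if self._loaded:
            return
        cfg = self.config
        self.peaksets = {}
        for sp, files in cfg.inputs.items():
            for key, path in files.items():
                assay, cond = key.rsplit("_", 1)
                self.peaksets[(sp, key)] = read_narrowpeak(
                    path, species=sp, assay=assay.replace("rela", "RELA").replace("atac", "ATAC"),
                    condition=cond,
                )
        self.omap = OrthologyMap.read_table(cfg.orthology_map)
        self.tracks = {
            name: SignalTrack.read_bedgraph(path)
            for name, path in cfg.tracks.items()
        }
        self.genes = read_genes_tsv(cfg.genes) if cfg.genes else None
        self.variants = read_variants(cfg.variants) if cfg.variants else None
        self.cell_sets = {
            ct: read_narrowpeak(path, species=ct, assay="RELA", condition="stimulated")
            for ct, path in cfg.cell_types.items()
        }
        self._loaded = True

    # ------------------------------ stages ------------------------------

    def stage_conserve(self) -> None:
        cfg = self.config
        ref_peaks = self.peaksets[(cfg.reference, "rela_stimulated")]
        others = {sp: self.peaksets[(sp, "rela_stimulated")] for sp in cfg.partners}
        self.conservation = classify_conservation(
            ref_peaks, others, self.omap, cfg.parameters["min_overlap"]
        )
        self.results["conservation"] = self.conservation.labels
        grid_rows = []
        for t in cfg.parameters["overlap_grid"]:
            lab = classify_conservation(ref_peaks, others, self.omap, t)
            grid_rows.append((t, int((lab.labels["n_species"] >= 2).sum())))
        self.results["conservation_grid"] = pd.DataFrame(
            grid_rows, columns=["min_overlap", "n_conserved"]
        )

    def stage_modes(self) -> None:
        cfg = self.config
        self.mode_assignments = {}
        for sp in (cfg.reference, *cfg.partners):
            self.mode_assignments[sp] = classify_modes(
                self.peaksets[(sp, "rela_stimulated")],
                self.peaksets[(sp, "atac_basal")],
                self.peaksets[(sp, "atac_stimulated")],
                self.peaksets[(sp, "rela_basal")],
            )
            self.results[f"modes_{sp}"] = self.mode_assignments[sp]

    def stage_preserve(self) -> None:
        cfg = self.config
        partner_modes = {sp: self.mode_assignments[sp] for sp in cfg.partners}
        self.results["preservation"] = preservation_table(
            self.mode_assignments[cfg.reference],
            partner_modes,
            self.conservation,
            cfg.partners,
        )

    def stage_se(self) -> None:
        cfg = self.config
        self.se_regions = {}
        rows = []
        for sp in (cfg.reference, *cfg.partners):
            regions, cutoff = call_superenhancers(
                self.peaksets[(sp, "rela_stimulated")],
                stitch_distance=cfg.parameters["stitch_distance"],
            )
            self.se_regions[sp] = regions
            for r in regions:
                rows.append(
                    (
                        sp, r.region_id, r.interval.chrom, r.interval.start,
                        r.interval.end, ";".join(r.constituents), r.signal,
                        r.rank, r.is_super,
                    )
                )
        self.results["superenhancers"] = pd.DataFrame(
            rows,
            columns=[
                "species", "region_id", "chrom", "start", "end",
                "constituents", "signal", "rank", "is_super",
            ],
        )
        ref_ses = [
            (r.region_id, r.interval)
            for r in self.se_regions[cfg.reference]
            if r.is_super
        ]
        other_ses = {
            sp: [(r.region_id, r.interval) for r in self.se_regions[sp] if r.is_super]
            for sp in cfg.partners
        }
        if ref_ses:
            se_cons = classify_se_conservation(
                ref_ses, other_ses, self.omap, cfg.reference
            )
            self.results["se_conservation"] = se_cons.labels

    def stage_toprank(self) -> None:
        cfg = self.config
        if "rela_basal" not in self.tracks or "rela_stimulated" not in self.tracks:
            return
        ref_peaks = self.peaksets[(cfg.reference, "rela_stimulated")]
        top_pre, top_post, cut_pre, cut_post = top_ranked_peaks(
            ref_peaks, self.tracks["rela_basal"], self.tracks["rela_stimulated"]
        )
        self.top_pre, self.top_post = top_pre, top_post
        self.results["top_ranked"] = pd.DataFrame(
            {
                "peak_id": ref_peaks.ids(),
                "top_pre": [pid in top_pre for pid in ref_peaks.ids()],
                "top_post": [pid in top_post for pid in ref_peaks.ids()],
            }
        )

    def stage_motifs(self) -> None:
        cfg = self.config
        if not cfg.peak_fasta:
            return
        sequences = read_peak_fasta(cfg.peak_fasta)
        pwm = read_jaspar_pfm(cfg.pwm or _default_pwm_path())
        bg = estimate_background(
            [s.seq for s in sequences], order=cfg.parameters["background_order"]
        )
        hits = scan_peaks(sequences, pwm, bg, cfg.parameters["motif_threshold"])
        self.results["motif_hits"] = hits
        ids = [s.peak_id for s in sequences]
        counts = motifs_per_peak(hits, ids, cfg.parameters["motif_half_window"])
        modes_ref = self.mode_assignments[cfg.reference]
        label = modes_ref.set_index("peak_id")
        count_df = counts.rename("n_motifs").reset_index().rename(columns={"index": "peak_id"})
        count_df["mode"] = count_df["peak_id"].map(label["mode"])
        count_df["prebound"] = count_df["peak_id"].map(label["prebound"])
        self.results["motif_counts"] = count_df
        # pairwise Mann-Whitney between mode groups, Bonferroni over pairs
        groups = {
            m: count_df.loc[count_df["mode"] == m, "n_motifs"].to_numpy()
            for m in ("O", "C", "OA", "CA")
        }
        groups["P"] = count_df.loc[count_df["prebound"], "n_motifs"].to_numpy()
        pairs = [(a, b) for i, a in enumerate(MODE_LABELS) for b in MODE_LABELS[i + 1 :]]
        rows = []
        for a, b in pairs:
            if len(groups[a]) == 0 or len(groups[b]) == 0:
                continue
            p = mann_whitney_two_sided(groups[a], groups[b])
            rows.append(
                (a, b, float(groups[a].mean()), float(groups[b].mean()), p,
                 bonferroni(p, len(pairs)))
            )
        self.results["motif_tests"] = pd.DataFrame(
            rows, columns=["group_a", "group_b", "mean_a", "mean_b", "p_raw", "p_adj"]
        )
        self.results["motif_profile"] = motif_density_profile(
            hits, ids, flank=200, binsize=20
        )

    def stage_enrich(self) -> None:
        cfg = self.config
        ref_peaks = self.peaksets[(cfg.reference, "rela_stimulated")]
        all_ids = set(ref_peaks.ids())
        modes_ref = self.mode_assignments[cfg.reference]
        conserved = self.conservation.conserved_ids()
        three_species = {
            pid
            for pid in conserved
            if self.conservation.category(pid, cfg.partners) == "B"
        }
        label_sets = {
            m: set(modes_ref.loc[_label_indicator(modes_ref, m), "peak_id"])
            for m in MODE_LABELS
        }
        results = []

        for m in MODE_LABELS:
            if not label_sets[m]:
                continue
            results.append(
                fe_conserved_within_type(
                    conserved, label_sets[m], all_ids,
                    label=f"conserved_within_mode_{m}", family_size=len(MODE_LABELS),
                )
            )

        se_ids = {
            pid
            for r in self.se_regions[cfg.reference]
            if r.is_super
            for pid in r.constituents
        }
        for m in MODE_LABELS:
            if not label_sets[m]:
                continue
            results.append(
                fe_within_se(
                    se_ids, label_sets[m], all_ids,
                    label=f"mode_{m}_within_se", family_size=len(MODE_LABELS),
                )
            )
        results.append(
            fe_within_se(se_ids, conserved, all_ids,
                         label="conserved_within_se", family_size=1)
        )

        if self.cell_sets:
            sharing = classify_cell_sharing(ref_peaks, self.cell_sets)
            self.results["cell_sharing"] = sharing
            pan = set(sharing.loc[sharing["class"] == "pan-cell", "peak_id"])
            if pan:
                for m in MODE_LABELS:
                    if not label_sets[m]:
                        continue
                    results.append(
                        fe_within_shared_class(
                            pan, label_sets[m], all_ids,
                            label=f"mode_{m}_within_pancell",
                            family_size=len(MODE_LABELS),
                        )
                    )
                results.append(
                    fe_within_shared_class(
                        pan, conserved, all_ids,
                        label="conserved_within_pancell", family_size=1,
                    )
                )

        if self.genes is not None:
            assignments = assign_to_tss(
                ref_peaks, self.genes, cfg.parameters["tss_half_window"]
            )
            self.results["tss_assignments"] = assignments
            classes = ("up", "down", "constitutive")
            fam = len(MODE_LABELS) * len(classes)
            for m in MODE_LABELS:
                if not label_sets[m]:
                    continue
                for cls in classes:
                    results.append(
                        fe_tss_general(
                            assignments, label_sets[m], all_ids, cls,
                            label=f"tss_{cls}_mode_{m}", family_size=fam,
                        )
                    )
            for cls in classes:
                results.append(
                    fe_tss_general(
                        assignments, conserved, all_ids, cls,
                        label=f"tss_{cls}_conserved", family_size=len(classes),
                    )
                )
                results.append(
                    fe_tss_bias_corrected(
                        assignments, conserved, cls,
                        label=f"tss_{cls}_conserved_corrected",
                        family_size=len(classes),
                    )
                )

        if self.variants is not None:
            var_types = {
                "three_species_conserved": three_species,
                "conserved": conserved,
                "prebound": label_sets["P"],
                "se_member": se_ids,
            }
            if hasattr(self, "top_pre"):
                var_types["top_ranked_pre"] = self.top_pre
            for name, ids in var_types.items():
                if not ids:
                    continue
                results.append(
                    fe_variant_overlap(
                        ref_peaks, self.variants, ids,
                        label=f"variants_within_{name}", family_size=len(var_types),
                    )
                )

        self.results["enrichment"] = pd.DataFrame([r.as_row() for r in results])

    # ------------------------------ driver ------------------------------

    def run(self, stages=None) -> dict:
        requested = list(stages) if stages else list(STAGES)
        bad = set(requested) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        ordered = [s for s in STAGES if s in requested]
        # implicit dependencies
        deps = {
            "preserve": {"conserve", "modes"},
            "enrich": {"conserve", "modes", "se"},
            "motifs": {"modes"},
        }
        needed = set(ordered)
        for s in ordered:
            needed |= deps.get(s, set())
        ordered = [s for s in STAGES if s in needed]
        self.load()
        for s in ordered:
            try:
                getattr(self, f"stage_{s}")()
            except Exception as exc:
                raise RuntimeError(f"stage {s!r} failed: {exc}") from exc
        return self.results

    def write(self) -> dict:
        outdir = self.config.output_dir
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, df in sorted(self.results.items()):
            path = os.path.join(outdir, f"{name}.tsv")
            df.to_csv(path, sep="\t", index=False)
            paths[name] = path
        manifest = {
            "package": "relascape",
            "version": __version__,
            "parameters": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.config.parameters.items()
            },
            "inputs": {
                os.path.basename(f): _sha256(f)
                for f in sorted(self.config.input_files())
                if f and os.path.exists(f)
            },
            "outputs": sorted(self.results),
        }
        mpath = os.path.join(outdir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        paths["manifest"] = mpath
        return paths


def run(config: PipelineConfig, stages=None, write: bool = True) -> PipelineRun:
    """Execute the pipeline; returns the populated :class:`PipelineRun`."""
    runner = PipelineRun(config)
    runner.run(stages)
    if write:
        runner.write()
    return runner
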