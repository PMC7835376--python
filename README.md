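# relascape

Cross-species analysis of NF-κB (RELA) binding landscapes.

During the acute inflammatory response, TNFα drives the NF-κB subunit RELA
into the nucleus, where it binds tens of thousands of genomic sites.  Which
of those binding events matter?  Two complementary filters help: **evolutionary
conservation** (does an orthologous peak exist in other mammals?) and
**chromatin context** (does RELA bind chromatin that is already accessible,
chromatin that opens only after stimulation, or nucleosome-occluded DNA?).
`relascape` implements the comparative-epigenomics toolchain behind this kind
of study for researchers working with ChIP-seq/ATAC-seq peak calls from
matched stimulated and unstimulated cells in multiple species:

* **Conservation calling** — peaks are projected through collinear alignment
  blocks (an orthology map) into each other species' coordinates; a peak is
  *conserved* when any projected fragment overlaps a peak there by at least
  `min_overlap` bp (1 bp by default, with a 1/20/50/100 robustness grid).
  Peaks that do not align are species-specific.
* **Binding-mode classification** — each stimulated RELA peak is labelled by
  its overlap with accessibility peaks before (−) and after (+) stimulation:
  Mode **O** (−/+ open), **OA** (opens after), **CA** (closes after), **C**
  (never accessible); orthogonally, Mode **P** (*prebound*) flags peaks that
  already overlap a basal RELA peak.
* **Mode preservation** — for conserved peaks, the observed fraction whose
  orthologous partner carries the same mode is compared against a five-term
  independence model.  With conservation categories B (all three species),
  C (reference + first partner) and D (reference + second partner), and
  p<sub>X</sub>(s, g) the conditional probability of mode X for species *s*
  in category *g*,

  P(A) = p<sub>X</sub>(H,B)·p<sub>X</sub>(M,B)·p<sub>X</sub>(C,B)·P(B)
  + p<sub>X</sub>(H,B)·p<sub>X</sub>(M,B)·(1−p<sub>X</sub>(C,B))·P(B)
  + p<sub>X</sub>(H,B)·(1−p<sub>X</sub>(M,B))·p<sub>X</sub>(C,B)·P(B)
  + p<sub>X</sub>(H,C)·p<sub>X</sub>(M,C)·P(C)
  + p<sub>X</sub>(H,D)·p<sub>X</sub>(C,D)·P(D),

  tested per mode with a two-sided exact binomial test (Bonferroni-adjusted).
* **Super-enhancers and top-ranked peaks** — ROSE-style calling: peaks within
  12.5 kb stitch into regions, regions are ranked by aggregate signal, and the
  super/typical cutoff is the slope-1 tangency of the min–max-scaled
  rank/signal curve.  The same inflection cutoff applied to per-peak signal
  (pre- or post-stimulation) defines *top-ranked* peaks.
* **Motif scanning** — matrix-scan-style PWM scoring (natural-log likelihood
  ratio against an order-0/1 Markov background, hits at weight ≥ 1, both
  strands), per-peak counts within ±100 bp of summits, and motif-density
  profiles.
* **Enrichment battery** — every fold enrichment is a ratio of ratios over a
  stated universe, e.g. (conserved type-X peaks / type-X peaks) ÷ (conserved
  peaks / all peaks), with chi-squared (Yates) or two-sided Fisher exact
  tests and per-family Bonferroni correction.  Includes cell-type-sharing
  classes (pan-cell … reference-specific), ±10 kb TSS association (with a
  bias-corrected variant computed over peaks near any gene), and noncoding
  variant overlap.
* **Synthetic-data generator** — multi-species peak landscapes with planted
  ground truth (conserved fraction, mode proportions, prebound structure,
  super-enhancer neighbourhoods, TSS/variant associations, motif placement)
  so every stage is testable without downloads, plus a null variant with all
  associations switched off.

## Worked example

Generate a small synthetic landscape (2,000 reference peaks, three species)
and run the full pipeline:

```python
from relascape.simulate import SyntheticConfig, generate
from relascape.pipeline import PipelineConfig, run

generate(SyntheticConfig.for_n_peaks(2000), seed=7, outdir="fixture")
runner = run(PipelineConfig.for_fixture_dir("fixture", "out"))

cons = runner.results["conservation"]
print("conserved fraction:", round((cons["n_species"] >= 2).mean(), 3))
enr = runner.results["enrichment"].set_index("label")
print(enr.loc[["conserved_within_mode_P", "mode_P_within_se", "tss_up_mode_P"],
              ["fold", "p_raw", "p_adj", "test"]].round(4))
```

prints

```
conserved fraction: 0.3
                           fold   p_raw   p_adj              test
label
conserved_within_mode_P  2.0000  0.0070  0.0350       chisq_yates
mode_P_within_se         2.7523  0.1627  0.8137       chisq_yates
tss_up_mode_P            2.5000  0.1892  1.0000  fisher_two_sided
```

The generator planted a 2× enrichment of conservation among prebound (Mode P)
peaks — recovered exactly and significant after Bonferroni correction — and
3× prebound enrichments inside super-enhancers and near upregulated-gene
TSSs, recovered within quantisation of the 20 prebound peaks at this small
scale (the folds sharpen to ≈3 at the default 10,000-peak size) but not
significant with only 20 prebound peaks.  The preservation table from the
same run shows modes O and C preserved across species well above the
independence expectation:

```
label   k   n  observed_frac  expected_frac   fold  p_adj
    O 242 345          0.701          0.613  1.145  0.004
    C 109 184          0.592          0.423  1.400  0.000
   OA   2  53          0.038          0.084  0.449  1.000
   CA   0  18          0.000          0.025  0.000  1.000
    P   5  12          0.417          0.010 43.312  0.000
```

The same analysis is available from the shell:

```bash
relascape simulate --seed 7 --n-peaks 2000 --out fixture
relascape run-all --fixture-dir fixture --out out
relascape se --fixture-dir fixture --out out_se   # single stage
```

Stage subcommands (`conserve`, `modes`, `preserve`, `se`, `toprank`,
`motifs`, `enrich`) accept either `--fixture-dir` or a YAML `--config`
naming arbitrary narrowPeak/bedGraph/TSV inputs; outputs are
self-describing TSVs plus a manifest with input checksums, and reruns on
identical inputs are byte-identical.

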