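# tmequant

Quantification toolkit for dissecting the tumor microenvironment (TME) of
preinvasive and invasive lung nodules from single-cell and spatial data.

Part-solid lung nodules pair a non-solid (NS, preinvasive) component with a
solid (S, invasive) component inside the same lesion, with adjacent normal
lung (NL) as an internal control. Profiling the three compartments of the
same patient — by scRNA-seq, multiplexed imaging mass cytometry (IMC) and
spot-based spatial transcriptomics — turns disease progression into a set
of paired, quantifiable contrasts. `tmequant` implements the bespoke
statistics those contrasts need:

* **BET triads** — an endothelial cell (EC) with at least one B cell *and*
  one T cell within 2x its major-axis length; an imaging proxy for
  high-endothelial-venule-mediated lymphocyte recruitment inside tertiary
  lymphoid structures (TLS). EC-centric counts, B x T contact-pair counts
  and per-mm^2 rates.
* **Neighborhood densities** — target-phenotype counts within a 100 um
  radius of anchor (e.g. tumor) cells, expressed as cells/mm^2; per-TLS
  densities and the activation/exhaustion ratio of CD4/CD8 T cells.
* **Single-cell QC** — keep cells with 200–6500 detected genes and <= 15%
  mitochondrial counts (boundaries inclusive); flag doublets that
  co-express markers of two or more cell lineages.
* **Module scores** — per-cell mean expression of a gene set minus the mean
  of expression-bin-matched control genes (24 bins, 100 controls per gene);
  tumor cells labeled AT2-like or club-like by the larger of the two
  cell-of-origin scores, aggregated into per-patient calls.
* **CNV cell scores** — per chromosome arm, the mean of squared CNV values;
  per cell, the arithmetic mean over arms. For Normal(0, sigma) noise the
  expected score is sigma^2; a single arm shifted by `a` among `k` arms
  scores exactly `a^2/k`. Clusters above the reference mean + 2 s.d. are
  called tumor.
* **Spot statistics** — spatial significance (across-spot s.d. of
  normalized expression), top-n candidate gene selection with cross-sample
  intersection, AUCell-style rank-recovery signature scores per spot, and
  Pearson cell-type coexistence matrices.
* **Comparison layer** — Wilcoxon matched-pairs signed-rank tests for
  compartments matched within patients (exact null up to n = 25), a
  Levene-gated Mann-Whitney/t-test for unpaired data, Kruskal-Wallis for
  three or more groups, and the `*` … `****` significance ladder.
* **Synthetic data** — generators for every input with recorded ground
  truth (planted triads, TLS disks, expression programs, arm shifts,
  spatially variable genes), so every detector can be scored by precision
  and recall without any external download.

## Worked example

```python
import tmequant as tq

cfg = tq.SimConfig(seed=1, n_triads_planted=7, n_distractors=5)
cells, truth = tq.simulate_roi(cfg)
contacts = tq.classify_contacts(cells)      # distance <= 2 x EC major axis
result = tq.detect_triads(contacts)
rates = tq.triad_rate(result, truth["roi_area_mm2"])
```

Running `python examples/01_bet_triads.py` prints:

```
simulated ROI: 3655 cells, 145 endothelial cells
detected 7 triads (7 B x T contact pairs), 3.11 triads/mm^2
planted triad ECs recovered: 7/7, false positives: 0
```

All 7 planted triads are recovered with no false positives: the 5
distractor ECs (whose second lymphocyte class sits just outside the
2x-axis boundary) are correctly ignored, and the rate normalizes the count
by the 2.25 mm^2 ROI area. The other scripts under `examples/` walk
through neighborhood densities and TLS ratios, QC + module scoring +
origin calls, CNV scoring, spot statistics, and the comparison layer, each
printing the quantities it computes and what they mean.

A thin CLI mirrors the library (`tmequant simulate|qc|score|cnv|density|
tls|triads|spots|compare|run`); `tmequant run` executes the full synthetic
pipeline and writes per-stage TSVs plus a JSON summary.

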