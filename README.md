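# emtstrat

Gene-signature scoring and EMT-spectrum stratification of breast-cancer
expression data, for computational biologists analysing single-cell or
bulk tumour transcriptomes.

Within a carcinoma, malignant cells occupy a spectrum of states from fully
epithelial to fully mesenchymal (the epithelial-to-mesenchymal transition,
EMT), and genes such as MCAM/CD146 are expressed heterogeneously across
that spectrum and across the tumour's other cell types (vasculature,
stroma, normal epithelium).  This package implements the score-based
stratification workflow used to dissect that heterogeneity:

* **EMT score (sEMT)** per observation i over expression values x_ig:

  ```
  sEMT_i = Σ_{g ∈ M} x_ig − Σ_{g ∈ E} x_ig
  ```

  with mesenchymal markers M = {CDH2, ZEB1, VIM, MMP1, FN1, TGFB1I1} and
  epithelial markers E = {CDH1, GRHL2, ITGB4, KRT5, KRT8, FST} built in;
  higher sEMT = more mesenchymal.
* **Mean-expression signatures** for invasion (sInv), cancer stem cell
  (sCSC) and angiogenesis (sAng) phenotypes, loaded from user-supplied
  gene-list files: `score_i = mean_{g ∈ G} x_ig`.
* **EMT classes** by half-open thresholds: low (sEMT < 0), med ([0, 5)),
  high (≥ 5) for log-normalised per-cell scores; 2,000 / 5,000 for
  linear-scale bulk tumours.  Boundaries can also be calibrated to the
  78th/96th percentiles of the observed score distribution.
* **MCAM tri-partition** within any grouping: non-expressers are `neg`,
  the ranked expressers split into equal `low` and `high` halves (odd
  counts put the extra cell in `low`).
* **Nine-subpopulation summary** (3 EMT × 3 MCAM classes) with mean sInv
  and sCSC per cell, and their Spearman correlation.
* **Nonparametric statistics**: exact/approximate two-tailed Mann-Whitney
  and Wilcoxon matched-pairs tests, Spearman correlation with Fisher-z
  confidence intervals, expressing-cell proportions, and per-sample mean
  methylation M-values with tumour-vs-normal comparison.
* **Synthetic data generator** producing single-cell atlases, bulk
  mixtures and methylation tables with known ground truth (latent EMT
  position per cell, vascular fraction per bulk sample), so every stage is
  testable at desk scale.

## Worked example

`examples/01_score_and_classify.py` builds three cells by hand and scores
them:

```
cell                 sEMT   class
epithelial_like       -8.4   low
hybrid_like            2.4   med
mesenchymal_like       7.8   high
```

`examples/03_synthetic_atlas_recovery.py` simulates an atlas (8,000
malignant + 1,500 normal epithelial + vascular/stromal/immune cells) and
recovers the generator's ground truth:

```
Spearman(sEMT, latent EMT position) = 0.886
class recovery after percentile calibration = 90.9%  (cuts at -3.34 and 6.30)
MCAM expressing malignant: 4.0% (322/8000)
MCAM expressing normal_epithelial: 10.5% (157/1500)
```

The correlation says the score orders cells along the latent spectrum
almost as well as the noisy, dropout-ridden expression values allow; the
expressing fractions confirm the generator's calibration (~4% of
malignant, ~10% of normal epithelial cells express MCAM).  The other
examples cover the MCAM tri-partition, the nine-subpopulation summary
(where, in hybrid-peak mode, the EMT-high/MCAM-low cell carries the
largest combined invasion + stemness mean), bulk angiogenesis-MCAM
coupling, methylation summaries, and the end-to-end pipeline.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
emtstrat simulate cells --seed 1 --outdir sim/
emtstrat score --matrix cells.tsv --signatures sigs.tsv --out scores.tsv
emtstrat stratify --scores scores.tsv --matrix cells.tsv --out strata.tsv
emtstrat report --strata strata.tsv --scores scores.tsv --out subpops.tsv
emtstrat run --config run.yaml       # everything end to end
```

Outputs are TSV with a JSON sidecar recording genes used, seeds and test
results.  Exit codes: 0 success, 2 configuration error, 3 data error.

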