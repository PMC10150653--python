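# Methods

## Scores

All scores operate on a non-negative observations × genes matrix with a
*declared* scale (`log_normalized` for per-cell data, `linear` for bulk);
the scale is never inferred, because the classification boundaries are
scale-specific and silently mixing them would corrupt every downstream
label.

**sEMT** is a sum-difference over twelve genes: the six mesenchymal
markers (CDH2, ZEB1, VIM, MMP1, FN1, TGFB1I1) summed, minus the six
epithelial markers (CDH1, GRHL2, ITGB4, KRT5, KRT8, FST) summed.  The
sign convention is mesenchymal-positive.  Because a missing term shifts
the score against fixed boundaries, sum-difference scoring refuses
matrices that lack any of the twelve genes unless explicitly overridden
(`allow_missing`), in which case the omission is recorded in the score
metadata.

**sInv, sCSC, sAng** are arithmetic means over their gene sets.  The
published invasion/stemness/angiogenesis panels are supplied as signature
files (three columns: signature_name, gene, set_role) rather than
hard-coded; the aggregation is inferred from the file (sum-difference iff
any negative-role rows exist).  Mean signatures average over the genes
present in the matrix, logging absentees — published panels rarely match a
matrix's gene universe exactly, and a mean is robust to a missing member
in a way a sum-difference is not.  The aggregation actually used is
recorded per signature in the run summary, since for the angiogenesis
score either a mean or a sum is defensible; the default here is the mean,
for consistency with sInv/sCSC (a sum only rescales the score and any
threshold applied to it).

MMP1 belongs to both the EMT and the stemness signature; the registry's
overlap report lists any such shared genes, and duplicate gene *columns*
in a matrix are an error rather than being averaged, so no sum can ever
double-count.

## Stratification

EMT classes use half-open intervals — low: (−∞, b₁), med: [b₁, b₂),
high: [b₂, ∞) — so that every real-valued score is classified and the map
is monotone.  Defaults are b₁ = 0, b₂ = 5 on log-normalised per-cell
scores and b₁ = 2,000, b₂ = 5,000 on linear bulk scores.  Exactly-0 and
exactly-5 scores fall in med and high respectively; an interval
convention had to be chosen, and half-open intervals leave no
unclassifiable band.  When fixed cuts do not suit a dataset,
`calibrate_emt_thresholds` places them at the empirical quantiles of the
observed score distribution at the cumulative mixture weights (78th and
96th percentiles by default) — boundaries set "according to population
distribution".

The MCAM tri-partition, within each group (by default the EMT class, but
any label column is accepted): observations at or below the detection
threshold (default 0 — "expressing" means value > 0) are `neg`; the
remaining expressers are sorted ascending and the first ⌈k/2⌉ become
`low`, the rest `high`, so |low| − |high| ∈ {0, 1} always.  Ties at the
median boundary are broken by stable input order, which makes the
partition deterministic and reproducible; no randomisation is involved.

The nine-subpopulation summary reports n and the arithmetic means of sInv
and sCSC per (EMT class, MCAM class) cell, including empty cells with
n = 0 and undefined (NaN) means, and the Spearman correlation of the mean
sInv against the mean sCSC across the defined cells (≥ 3 required).

## Statistics

* Two-tailed exact p-values are 2 × the one-tail probability, capped at 1
  — the convention of the mainstream statistics packages this field uses.
* Mann-Whitney: U of the first sample; exact when n₁ + n₂ ≤ 25 and the
  pooled sample has no ties, otherwise a normal approximation with tie
  and continuity corrections.  The `method` field records which path ran.
* Wilcoxon matched pairs: zero differences are dropped (all-zero input is
  a degenerate-data error, not p = 1); W = min of the two signed-rank
  sums.  The exact path covers ≤ 25 nonzero differences *including tied
  |d|*, via a characteristic-polynomial convolution over doubled midranks
  — mathematically identical to enumerating all 2ⁿ sign patterns but
  polynomial time.  Beyond that, the tie-corrected normal approximation.
* Spearman: r on average ranks; p from t = r·√((n−2)/(1−r²)) on n−2
  degrees of freedom; 95% CI from the Fisher z transform,
  z ± z_{0.975}/√(n−3) back-transformed (reported as the full [−1, 1]
  for n = 3, where the transform is undefined).  At r = ±1 the CI
  degenerates to [r, r] and p is reported as the smallest positive float
  rather than 0 — the Fisher z is infinite there and NaN must never
  escape.  p-values from any test are likewise clamped into (0, 1].
* No multiple-testing correction is applied anywhere; the pairwise tests
  per figure-style analysis are reported raw.
* Methylation: per-sample mean M-value over available (non-NaN) probes;
  samples with no available probe are excluded with a warning.  Group
  comparison delegates to the Mann-Whitney test; the
  methylation-expression coupling to the Spearman machinery (≥ 4 matched
  samples required; unmatched sample IDs are dropped and logged).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
it makes no attempt to fit any real atlas.

* **Latent spectrum.** Each malignant cell draws a class from weights
  (0.78, 0.18, 0.04) and a latent position t ∈ [0, 1] from the class's
  Beta component — Beta(1.5, 10), Beta(6, 6), Beta(12, 2) for the
  epithelial-like, hybrid and mesenchymal-like classes.  Normal
  epithelial cells are all class 1.  Cell-type counts default to 20,000
  malignant, 3,000 normal epithelial, 1,000 endothelial, 500
  perivascular, 1,000 CAF, 4,000 immune.
* **Expression model.** On the log-normalised scale, a gene with
  cell-level mean μ yields value = dropout(max(0, μ + N(0, σ))) with
  σ = 0.4, where dropout zeroes the value with probability
  1 − min(1, μ/d₀).  Epithelial genes have μ = m_E(1 − t), mesenchymal
  genes μ = m_M·t, with m_E = m_M = 2.0.  This truncated-Gaussian +
  dropout model (rather than count-level negative binomial) is chosen
  because the analysis consumes log-normalised values and never touches
  counts, and it keeps the oracles analytic.  The dropout scale was
  calibrated to d₀ = 2.0 so that the generator meets its recovery
  contract — Spearman(sEMT, t) ≈ 0.88, percentile-calibrated class
  recovery ≈ 0.91 — while the fixed 0/5 boundaries still carve the
  simulated score distribution into a large epithelial-like, a moderate
  hybrid and a small mesenchymal-like class.
* **MCAM.** In the epithelial lineage MCAM is gated by a Bernoulli with
  probability base + 0.15·t, the per-cell-type base solved analytically
  so the expected expressing fraction equals the target (4% malignant,
  10% normal epithelium) under the configured mixture — the calibration
  survives any change to the mixture.  Expressed levels are drawn from a
  normal with mean 3.0·t + 0.2 truncated to (0, ∞); truncation (rather
  than clipping at 0) keeps every gated cell an expresser, so the gate
  alone controls the expressing fraction.  Endothelial and perivascular
  cells express MCAM (and KDR / CSPG4 respectively) at a mean of 3.5 —
  the vascular level is a free parameter, documented as such, since only
  "high" is known.
* **Validation markers.** OVOL2 and ESRP1 decline with t, TWIST1, QKI and
  S100A4 rise with t (amplitude 2.0); EPCAM is higher in malignant (2.5)
  than normal epithelium (1.5); 200 decoy genes carry independent noise.
* **Invasion/stemness genes** rise linearly with t by default.  In
  `hybrid_peak` mode their mean follows a Gaussian bump centred at
  t = 0.75 (width 0.12), which reproduces qualitatively the observation
  that the EMT-high / MCAM-low subpopulation — enriched for cells just
  below the fully mesenchymal extreme — carries the maximum combined
  invasion + stemness mean.
* **Bulk mixtures.** Each of 500 samples draws a vascular fraction
  v ~ Beta(2, 8), split evenly between endothelial and perivascular
  compartments; the remainder splits 0.6/0.1/0.3 across
  malignant/normal-epithelial/stroma.  Per-sample malignant EMT
  composition comes from a Dirichlet around the cohort weights
  (concentration 2), giving realistic between-tumour spread.  The bulk
  value per gene is the weighted sum of compartment expected profiles
  (stroma expresses the mesenchymal markers at amplitude 3.0 — VIM and
  FN1 are classic fibroblast genes) scaled by 1,000 with multiplicative
  log-normal noise (σ = 0.1), so bulk sEMT spans roughly −2,000 to
  8,000 and the 2,000/5,000 boundaries are meaningful.  Angiogenesis
  genes scale with v; bulk MCAM receives vascular plus
  malignant-expresser contributions.
* **Methylation.** Nine probes per sample, M ~ N(a − b·expr, 0.3) with
  a = 2, b = 1.5; the cohort helper draws tumour expression lower
  (mean 0.6) than normal (1.6), so tumours show higher M.
* **Determinism.** One seeded generator per simulator with a fixed draw
  order; identical config + seed reproduces outputs byte for byte (bulk
  and methylation derive fixed offsets from the seed so the three
  simulators are independent but jointly reproducible).

### What passing tests do and do not show

The generator produces clean, unimodal, linearly-coupled structure: no
batch effects, doublets, patient structure, UMI noise, or alias/HGNC
symbol mess.  Tests passing on it demonstrate that the scoring,
stratification and statistical machinery is correct and that the analysis
recovers structure *when the assumed structure is present* — not that the
fixed thresholds or signatures are biologically optimal on any real
dataset.  Real single-cell atlases will show weaker score-latent coupling
and require percentile recalibration of the boundaries.

## Problem sizes

The test suite runs the full default-scale atlas (20,000 malignant cells)
once for the recovery checks, a 10,000-cell partition-invariant check,
and exhaustive enumeration oracles up to n₁+n₂ = 8 (Mann-Whitney) and
n = 10 (Wilcoxon); the whole suite completes in a few seconds, and
`scripts/acceptance.py` in a few seconds more.

## Known limitations

* Gene symbols are matched case-insensitively after upper-casing; no
  alias or HGNC resolution is attempted, so panels using retired symbols
  simply count as missing.
* The bulk simulator works on expected compartment profiles, not sampled
  cells, so it understates within-compartment sampling noise.
* The Fisher-z CI is approximate for small n and ties; the t
  approximation for the Spearman p is the standard large-sample form, not
  an exact permutation p.
* Survival analysis, count-level normalisation, embedding/visualisation
  and any web-service access are out of scope by design; the pipeline
  consumes pre-normalised matrices.
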