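# Methods

This note documents the models, numerical choices, and generator
assumptions behind `epiorigin`, in the spirit of the methods documentation
of packages like statsmodels or msprime. Everything stated here is
computed by the test suite or `scripts/acceptance.py`; no empirical claim
below goes beyond what the code measures.

## Coordinates, β values, and missingness

All genomic coordinates are 0-based half-open. Manifests delivered 1-based
are converted on load (`read_manifest(..., one_based=True)`). β values are
methylation fractions M/(M+U+100); the +100 offset keeps β strictly below 1
at finite intensity and equal to 0 at zero signal. Missing β is `NaN`
throughout and is never conflated with hypomethylation: region means skip
missing probes, binarization preserves `NaN`, and dissimilarities only use
co-covered sites. "Low-detected" probes enter as a precomputed boolean
flag rather than being recomputed from raw array intensities — detection
p-values belong to the array-preprocessing layer, which is out of scope
here.

## Stratification

Probes map to a region when start ≤ pos < end. Regions within one class
are disjoint by invariant, so a probe maps to at most one UK and one DK
region; a probe under both classes contributes to both, since the classes
are always analyzed separately. Per-region β is the arithmetic mean over
non-missing probes.

Clustering is agglomerative with complete linkage and Euclidean distance
over region-mean vectors, cut at the final merge (k = 2): the biological
model is explicitly bimodal, so no height-based cut is used. The
**cluster-to-label rule** is healthy-majority: healthy epidermis largely
reflects the methylome of terminally differentiated keratinocytes, so the
branch holding the strict majority of healthy samples is the
keratinocyte-like side. An exact 50/50 healthy split raises an
`AmbiguousHealthyAnchorError` rather than guessing. Clustering operates on
unscaled region means (row scaling is a display concern); samples missing
more than 20% of the selected regions are dropped with a warning, and
remaining regions with any missing value are excluded so distances are
computed on complete vectors.

External cohorts are classified by concatenating them with the healthy
reference, restricting to shared probes (error if fewer than 50% of the
reference's region-mapped probes survive), and re-running the same
region-averaging and clustering.

The moderated two-group t (`dmp_test`) shrinks per-probe residual
variances toward a pooled prior. The prior degrees of freedom d0 and prior
variance s0² are fitted by method of moments on log residual variances:
under the scaled-F sampling model, var(log s²) = ψ′(d/2) + ψ′(d0/2), so d0
comes from inverting the trigamma function (Newton iteration), and s0²
from the matching mean identity. `prior_df=0` recovers the ordinary t and
`prior_df=inf` the fully pooled t — both limits are exercised against
closed forms in the tests. The significance flag uses the raw p < 0.05
rule; BH-adjusted q values are reported alongside.

Rank-sum comparisons everywhere (marker scores, chromatin states,
fractions) use the exact Mann-Whitney null for combined n ≤ 25 without
ties, otherwise the normal approximation with continuity correction; a
fully degenerate comparison (all pooled values identical) short-circuits
to p = 1.

## Single-cell integration

Bulk β is binarized at 0.5 (inclusive above) to match the binary nature of
single-cell CpG calls. The dissimilarity between two entities is the
mismatch fraction over sites covered in both (normalized Hamming) — the
natural metric on binary calls, degrading gracefully under sparsity. Pairs
sharing fewer than `min_shared` = 50 sites are reported missing and, before
MDS, imputed with the maximum observed dissimilarity (a deliberate
"no evidence of affinity" fill, flagged in the matrix). At the default
synthetic universe of ~36,000 CpGs, even the lowest-coverage cells (0.14%)
share ≥ 50 sites with every full-coverage bulk, so cell–bulk distances are
always defined; it is the cell–cell pairs that are sparse.

Classical MDS is Torgerson double centering: eigendecomposition of
−½ J D² J, top-two positive eigenpairs, with eigenvalues below 10⁻¹² of
the leading one treated as zero. Axes are oriented so each axis's
largest-magnitude coordinate is positive, making embeddings reproducible
up to that convention.

Cells are classified by comparing mean dissimilarity to the EpSC-like
bulks against the keratinocyte-like + healthy bulks; ties break to
Keratinocyte (the overwhelming majority class in epidermis) and are
flagged, and a cell with no usable distance to one side is reported
unclassifiable rather than forced.

ChromHMM summaries average calls (or β) over the CpGs falling in each of
the 15 states' intervals; a state with no covered CpG is missing for that
entity, and state means are invariant to splitting a state's intervals.
The enhancer comparison averages states 4 and 5 per entity before the
rank-sum test.

## Accessibility

Differential accessibility uses a two-sided Wilcoxon rank-sum on counts
normalized to the median per-cell depth. The upstream tool this mirrors
delegates to an unspecified package default, so the test and thresholds
here are declared, not inferred: q < 0.05 (BH), |log2FC| > 0.25 with a
pseudocount of 1 on normalized means (avoiding infinities at zero
detection), and detection fraction ≥ 5% in the favored cluster. Swapping
cluster labels flips fold-change signs and the UK/DK classes with
identical p-values.

Motif over-representation is the upper-tail hypergeometric probability
P[X ≥ k] with BH correction across motifs, against a background of all
tested regions outside the foreground, with no GC matching — sequence
composition is not modeled in the synthetic universe, a documented
divergence from sequence-aware motif tools. The implementation is checked
against exhaustive enumeration for every feasible configuration with
N ≤ 30.

## Mitotic clock

The clock model treats each clock CpG as starting at ground-state
methylation δ_i and gaining methylation with probability p_i per stem-cell
division: E[β_i | T] = δ_i + (1 − δ_i)(1 − (1 − p_i)^T). Clock parameters
(δ_i, p_i) are **inputs**, not refitted — the analysis uses a published
clock, it does not train one; synthetic runs take them from the generator.
T is estimated per sample by least squares over T ≥ 0: a coarse grid
bracket, bounded Brent, then a Newton polish on the gradient (Brent alone
stalls at √ε relative precision, too coarse at T in the thousands). β
below the ground state is clamped to zero excess before the per-CpG
closed-form inversion T_i = log(1 − (β_i − δ_i)⁺/(1 − δ_i)) / log(1 − p_i),
which is exposed for diagnostics. Samples whose β never exceeds δ return
T̂ = 0 with an `at_floor` flag. Group SCDR is the median of per-sample
T̂/age — robust to the right skew of mitotic-age distributions.

## Deconvolution

A gene is a marker for its highest-expressing cell type when that
expression is at least 2-fold above the runner-up and its specificity
score (number of types above the expression threshold, default 10% of the
table maximum) is at most 3; marker weight is 1/score. These score and
weight definitions are deliberate simplifications of the reference-based
tool they mirror — adequate for synthetic validation, not for
byte-matching its output. Markers keep their promoter methylation only if
it anti-correlates with expression across types (Spearman ρ < 0), encoding
the promoter-methylation-silences assumption; the cross-atlas imputation
of the original workflow is replaced by this supplied paired table.
Fractions come from weighted NNLS followed by renormalization onto the
simplex — simple and deterministic at this scale, an approximation
relative to a fully constrained solver, with exactness at zero noise
verified in the tests.

## The synthetic generator

All generators are pure functions of (config, seed), with independent
per-stage RNG streams, and emulate the study conditions the analysis
assumes:

* **Cohort**: 12 healthy, 55 tumors (22 EpSC-like / 33 keratinocyte-like;
  entity labels 20 AK / 35 cSCC drawn independently of subclass).
* **Regions/probes**: 914 UK regions (501 bp) and 864 DK regions (301 bp)
  over chr1–22; Poisson probe counts per region tuned to expected totals
  of 2,925 (UK) and 1,426 (DK); UK probes biased to CpG-island/promoter
  contexts and DK probes to open-sea/body-intergenic contexts; 32,000
  background probes; two hypermethylation-marker promoter blocks
  (MIR200C/141 and MIR205, 8 probes each); a handful of sex-chromosome and
  SNP/cross-reactive flagged probes to exercise filtering. UK regions are
  longer than DK regions by design, which is what makes more probes land
  in them.
* **Bulk β**: mean-parameterized beta noise (concentration 30, respecting
  [0, 1] support without truncation) around a class-mean table — UK: 0.60
  healthy/keratinocyte-like vs 0.20 EpSC-like; DK: 0.25 vs 0.70;
  background 0.5; marker promoters 0.80 in EpSC-like vs 0.20 elsewhere.
  The table is a calibration choice producing clear but non-trivial
  separation, not a measured effect size (none is published at region
  resolution).
* **Cells**: 554 cells, EpSC with probability 1%; coverage drawn from a
  scaled beta distribution on [0.14%, 6.88%] with mean 0.85%; calls are
  Bernoulli with cell-type means of 0.05/0.95 at UK and 0.95/0.05 at DK.
  The cell-level means are sharper than the bulk table on purpose: a
  single genome's CpG is essentially methylated or not, while bulk β is
  attenuated by cell-mixture averaging. Calls are generated at manifest
  probe positions only, keeping the joint embedding exact and desk-scale.
* **Clock**: 500 CpGs, δ ~ U(0, 0.2), p log-uniform on [10⁻⁴, 10⁻³]
  (chosen so the gain term stays identifiable — well off saturation — at
  mitotic ages up to a few thousand divisions), noise concentration 200;
  division rates 10.35 (healthy), 25 (EpSC-like), 39.7 (keratinocyte-like)
  divisions/stem cell/year; ages U(30, 90).
* **Deconvolution**: four keratinocyte populations (Basal1, Basal2,
  Spinous, Granular), 20 planted markers each plus broadly expressed
  housekeeping genes that the specificity cap must exclude; 50 Dirichlet
  mixtures, basal-heavy in the first half and suprabasal-heavy in the
  second, with σ = 0.02 clipped Gaussian bulk noise.
* **Accessibility**: 200 + 200 cells, gamma-Poisson counts with lognormal
  depth factors, 4-fold planted accessibility for UK regions in the
  undifferentiated cluster and DK regions in the differentiated one, plus
  1,000 flat null regions.
* **Segmentation**: UK regions become promoter states 1–2, DK regions
  strong-enhancer states 4–5, and the background band is tiled with 1 kb
  windows cycling through the remaining states — consistent with the
  planted biology, so enhancer hypomethylation in keratinocyte-type cells
  is observable in the state summary.

### What the generator does not emulate

No read-level data (FASTQ), bisulfite conversion errors, donor batch
effects, tumor purity variation, copy-number effects on β, realistic
linkage between neighboring CpGs, or sequence content (hence no GC-matched
motif backgrounds). Passing tests therefore demonstrate the correctness
and statistical behavior of the pipeline under its stated model — not
robustness to the artifacts of real array or sequencing data.

## Problem sizes and determinism

Default test and acceptance runs use the full emulated scale (36k-probe
universe, 67 bulks, 554 cells, 400 ATAC cells, 50 mixtures) — small enough
to run in seconds per stage on one CPU. Recovery-style checks use fixed
seed sets; property tests run hypothesis in derandomized mode. All
generator outputs are byte-identical under a repeated seed.

## Known limitations

* The healthy-majority labeling rule needs at least one healthy sample and
  fails (deliberately) on an even split.
* The moderated t covers the two-group design only; paired or multi-factor
  designs are out of scope.
* Simplex projection by renormalization after NNLS can differ from a fully
  constrained least-squares solution when residuals are large.
* The MDS imputation of sparse pairs with the maximum dissimilarity
  compresses cell–cell geometry at very low coverage; cell classification
  intentionally bypasses the embedding and uses cell–bulk distances
  directly.
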