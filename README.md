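# epiorigin

Cell-of-origin stratification of keratinocyte-cancer methylomes at
accessibility-defined regulatory regions.

## The problem

Cutaneous squamous cell carcinoma (cSCC) and its precursor actinic
keratosis (AK) can arise from different epidermal cell populations, and the
cell of origin leaves a durable imprint on the tumor's DNA methylome at
regulatory regions. `epiorigin` implements a desk-scale, fully tested
version of that analysis for epigenomics researchers:

1. **Region summarization & stratification.** Array probes (β values,
   β = M/(M+U+100)) are mapped into two sets of chromatin regions —
   accessible exclusively in *undifferentiated* keratinocytes (UK) or in
   *differentiated* keratinocytes (DK). Per-region mean β vectors are
   clustered hierarchically (complete linkage, Euclidean) and cut into
   k = 2. The branch holding the strict majority of healthy epidermis
   samples is called **keratinocyte-like**; tumors on the other branch are
   **EpSC-like** (epidermal-stem-cell-like). External cohorts are
   classified by co-clustering with the healthy reference over shared
   probes.
2. **Single-cell integration.** Sparse binary single-cell methylomes
   (sci-MET-style, ~0.85% CpG coverage) are combined with bulk methylomes
   binarized at β ≥ 0.5; pairwise normalized-Hamming dissimilarities over
   co-covered sites feed a classical (Torgerson) MDS embedding, and each
   cell is assigned to the nearer tumor subclass. Methylation is also
   summarized over 15 ChromHMM chromatin states (states 4–5 = strong
   enhancers) with Wilcoxon rank-sum comparisons between groups.
3. **Accessibility.** Differential accessibility between undifferentiated
   and differentiated cell clusters (rank-sum on depth-normalized counts,
   BH-corrected, fold-change and detection-fraction thresholds) and
   upper-tail hypergeometric motif over-representation in the resulting
   peak sets.
4. **Mitotic clock.** Per-sample mitotic age T (cumulative stem-cell
   divisions) from clock CpGs under the gain model
   β_i(T) = δ_i + (1 − δ_i)(1 − (1 − p_i)^T), fitted by bounded least
   squares; the stem-cell division rate is SCDR = T / chronological age.
5. **Deconvolution.** Keratinocyte-population fractions in bulk methylomes
   via an expression-derived marker reference (marker specificity score ≤ 3),
   an anti-correlation-filtered promoter-methylation reference, and
   weighted non-negative least squares projected onto the simplex.
6. **Synthetic data.** A first-class generator (`epiorigin.simulate`)
   produces every input with known ground truth — cohort of 12 healthy /
   55 tumor methylomes, ~914 UK / ~864 DK regions with ~2,925 / ~1,426
   mapped probes, 554 cells at ~1% EpSC prevalence, clock cohorts at
   class-specific division rates — so every stage is testable without any
   external download.

## Worked example

```python
from epiorigin import simulate as sim, stratify as strat, scmeth, clock as ck

cfg = sim.SynthConfig(seed=1)
regions, manifest, _ = sim.generate_regions_and_manifest(cfg)
bulk, truth = sim.generate_bulk(cfg, regions, manifest)

prmap = strat.map_probes_to_regions(manifest, regions)
print("mapped probes:", prmap.class_probe_totals().to_dict())

rbeta = strat.region_beta(bulk, prmap)
healthy = [s for s in bulk.sample_ids if truth.sample_subclass[s] == "healthy"]
res = strat.hierarchical_stratify(rbeta, healthy, region_class_filter="UK")
print("tumor subclasses:", res.tumor_labels().value_counts().to_dict())

cells, truth_c = sim.generate_cells(cfg, manifest, regions)
calls = scmeth.combine_profiles(cells, scmeth.binarize(bulk), manifest)
d = scmeth.pairwise_dissimilarity(calls)
labels = scmeth.classify_cells(d, res)
print("cells labeled EpSC:", (labels["label"] == "EpSC").sum(), "of", len(cells))

clock_beta, ages, truth_k = sim.generate_clock_samples(cfg)
est = ck.fit_mitotic_age(clock_beta, truth_k.clock_model)
g = ck.group_scdr(ck.scdr(est, ages), truth_k.sample_subclass)
print("group SCDR:", g.round(2).to_dict())
```

prints

```
mapped probes: {'DK': 1473, 'UK': 2950}
tumor subclasses: {'Keratinocyte-like': 33, 'EpSC-like': 22}
cells labeled EpSC: 4 of 554
group SCDR: {'epsc_like': 25.0, 'healthy': 10.37, 'ker_like': 39.68}
```

Reading the output: ~2,950 probes fall in UK regions and ~1,473 in DK
regions; clustering on the UK region means splits the 55 tumors into 33
keratinocyte-like and 22 EpSC-like samples (matching the planted truth);
4 of 554 single cells co-cluster with the EpSC-like bulks (the generator
drew 4 true EpSC cells at 1% prevalence); and the recovered group division
rates — 10.37 divisions/stem cell/year in healthy epidermis, 25.0 in
EpSC-like and 39.68 in keratinocyte-like tumors — match the generating
rates to within the noise.

A command-line interface mirrors the library:
`epiorigin simulate | stratify | atac-diff | motif-enrich | scmeth-embed |
chromhmm-summary | clock | deconv` (see `epiorigin COMMAND --help`).

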