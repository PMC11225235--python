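# Methods

This note documents the models, parameter choices and numerical conventions
behind `cfdeconv`, and what the synthetic validation does and does not show
about real data.

## Mixture model and deconvolution

A sample's cluster-level methylation vector b ∈ [0,1]^n is modelled as a
nonnegative combination of reference profiles, b ≈ A x with x ≥ 0, where the
columns of A are reference samples annotated with a tumor entity or a
non-tumoral background (healthy plasma cfDNA, white blood cells). We solve
the NNLS problem min ‖Ax − b‖₂ s.t. x ≥ 0 (active-set solver from
`scipy.optimize.nnls`) and report w = x / Σx as relative contributions.
When Σx = 0 (possible only for b ⟂ the column cone, e.g. b = 0) the result
is flagged degenerate and no entity is predicted.

Entity fractions sum the weights of columns sharing a label. The estimated
tumor fraction (ETF) is the summed weight of tumoral entities — equivalently
one minus the non-tumoral fraction, since w is normalized. Because the
normalization convention is a genuine free choice, the output also carries
the tumoral weights re-normalized among themselves
(`tumor_relative_fractions`). The predicted entity is the argmax over
tumoral entities only; exact ties (within 1e-12) are broken
lexicographically and flagged — a tie has no scientific meaning and the rule
only guarantees determinism.

**Missing data.** A cluster enters the design only if it is observed in the
sample *and* in every atlas column (complete-case). Missing betas are never
imputed; a pairwise-deletion mode was considered and rejected because NNLS
requires one complete design matrix, so pairwise handling would force
imputation through the back door. A floor of `min_clusters = 50` jointly
covered clusters (configurable) guards against fitting on too little
evidence; below it the deconvolver raises rather than returning a fragile
estimate. An optional uniform-beta (0.5) "unknown" column can absorb
unmodeled signal; it defaults off because it competes with genuine
intermediate-methylation signal.

**Correctness check.** Any x ≥ 0 factors as x = t·w with w on the unit
simplex and t = Σx, so the direction of the NNLS optimum equals the argmin
over simplex directions of min_{t≥0} ‖tAw − b‖². The test suite and the
acceptance script exploit this: an exhaustive grid over simplex directions
(step 1e-3) with the scale solved in closed form
(t* = max(0, ⟨Aw, b⟩/‖Aw‖²)) must agree with the normalized NNLS weights to
2e-3 per coordinate. Note that a grid search constrained to Σx = 1 *without*
profiling the scale answers a different question and does not agree with
normalized NNLS in general.

## Atlas construction

Clusters are the internal fragments of an in-silico MspI digest (cut C^CGG)
retained in a size window, default [20, 200] bp — the assay's enrichment
window is protocol-dependent, so the window is configurable, and a region
list may also be supplied directly as BED. Terminal fragments (lacking a
second cut site) are discarded. Array probes are assigned to clusters by
half-open containment; each reference cell is the **median** of the sample's
probe betas in the cluster, with clusters backed by fewer than
`min_probes_per_cluster` probes left missing for that column. One column per
reference sample is kept (entity aggregation happens after deconvolution) to
preserve within-entity heterogeneity; a per-entity-median collapse is
available as an option. Background columns are appended with
`is_tumoral = False` and must live on the same cluster universe.

All internal coordinates are 0-based half-open; 1-based inputs (Bismark
coverage, probe manifests) are converted at the reader boundary.

## Sample quantification and QC

Per-CpG betas are count_meth/(count_meth+count_unmeth) after merging
duplicate-position rows (sum of counts), making the result invariant to
record order and strand-split files. The cluster beta is the median of
per-CpG betas (a pooled-count alternative is exposed for sensitivity
analysis); defaults `min_depth_per_cpg = 1` and `min_cpgs_per_cluster = 3`
are deliberately permissive because real CSF libraries run at very low
input, and both are surfaced in the QC report.

cfDNA fraction = mass in [70, 700] bp / total mass, bounds inclusive,
scale-invariant. Bisulfite conversion = unmethylated / total calls over the
lambda spike-in chromosomes (default names `lambda`, `J02459.1`); absence of
lambda reads yields a missing-QC flag, not an error.

## Confidence gate

A classification is *confident* iff cfDNA fraction ≥ 0.40 AND ETF ≥ 0.30,
both inclusive. These are exploratory defaults: they mark the quality regime
in which methylation classification of CSF cfDNA has been observed to be
reliable, not validated clinical cutoffs, and both live in the config. A
missing cfDNA fraction (no fragment profile) is low confidence with an
explicit reason. The gate is monotone by construction: raising either
threshold can only demote samples.

## CNV profiling

Counts in fixed bins (default 400 kb; the last bin per chromosome may be
short; read-start counting) are scaled to a common autosomal total (1e6),
then compared with a ≥3-sample panel of normals via per-bin median and MAD
(scaled by 1.4826 to estimate a Gaussian sigma, floored at 1e-6);
log2 ratio = log2(sample/median), z = (sample − median)/spread. Bins with
scaled panel median below `min_panel_median` (default 10) and sex-chromosome
bins are masked — the panel's sex composition is unknown, and median/MAD was
chosen over a learned normalization because it is robust, fully specified
and directly testable. No GC correction is applied by default: the
restriction-based library preparation biases sample and panel identically,
so the panel cancels it.

Segments are maximal runs of ≥ `min_bins` (default 5) consecutive unmasked
bins with z beyond ±`z_threshold` (default 3) and consistent sign; a masked
bin breaks a run. Profile comparison calls two same-direction segments
shared when their overlap covers ≥ 50% of the shorter one.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the real study conditions:

- **Atlas**: per-region baseline beta shared by all components, plus
  disjoint marker regions per entity where the owner's beta differs by
  exactly `margin` (default 0.5, hypo- or hypermethylated at random). The
  margin parameter exists precisely to let tests degrade separability.
- **Reads**: per-region totals ~ Poisson(coverage), methylated counts ~
  Binomial(total, mixed beta) — the simplest model consistent with
  bisulfite counts. An optional beta-binomial `dispersion` parameter adds
  overdispersion (mean-preserving); it defaults off.
- **Mixtures**: one tumor entity at weight f plus two backgrounds. The
  cfDNA fraction c is coupled to f as c = f + (1 − f)·U(0,1), with the
  high-molecular-weight share (1 − c) assigned to the WBC background: HMW
  contamination from lysed cells dilutes tumor signal, so poor-quality
  samples carry weak tumor weight — the regime the gate is meant to flag.
- **Fragment profiles**: cfDNA mass on a truncated Gaussian at mode 167 bp
  (sd 40) inside [70, 700] bp; HMW mass on a Gaussian at 1500 bp (sd 300)
  above 700 bp; 1-bp bins make the size gate exact and mass is conserved to
  machine precision. The 167-bp mononucleosomal mode is a plasma-literature
  assumption — CSF fragmentomics are not well characterized — and is used
  only to place mass inside the gate.
- **CNV**: bin expectation depth × (1 + tf·(ratio − 1)) inside segments,
  Poisson counts, Poisson panel.

Real data differ in ways the simulation does not capture: within-entity
reference heterogeneity, correlated (not independent) coverage, bisulfite
conversion failure, mapping artifacts, and background cell types absent
from the atlas (e.g. damaged ventricular tissue under hydrocephalus).
Passing the synthetic suite therefore demonstrates the pipeline's
*computational* correctness and its behaviour under the stated noise model,
not clinical performance.

## Validation problem sizes

The acceptance checks use a 90-sample cohort (10 per tumor-fraction level
0.1–0.9; 8 tumor entities + 2 backgrounds; 2,000 clusters; 40
markers/entity at margin 0.5; region coverage 30) for deconvolution and
gating, 100 random instances (≤ 20 clusters, ≤ 3 columns) for the NNLS
oracle, and 100 replicate two-chromosome genomes (125 bins of 400 kb each)
with a 20-bin 1.5× gain at depth 1000 against a panel of 10 for CNV
recovery and the null false-positive rate. These sizes give stable
statistics (binomial SE on a 95% recovery criterion ≈ 2% at n = 100) while
keeping the whole suite fast enough to run routinely.

## Known limitations

- The entity prediction is an argmax without calibrated confidence scores;
  the gate is a proxy, not a posterior.
- Complete-case cluster filtering ties the usable cluster set to the most
  sparsely covered atlas column; a very patchy reference column shrinks the
  design for every sample (drop such columns upstream).
- The CNV caller is a run-length rule, not a segmentation model; it will
  split a true segment interrupted by a masked bin and has no sub-bin
  breakpoint resolution (boundary error is at bin granularity).
- ETF from deconvolution and tumor fraction from CNV amplitude are not
  reconciled; the latter is out of scope.
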