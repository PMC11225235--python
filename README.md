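# cfdeconv

Methylation-based tumor classification and tumor-fraction estimation for
cell-free DNA (cfDNA), with QC gating and shallow copy-number profiling.

## The problem

Pediatric central nervous system tumors are diagnosed from tissue biopsies,
which can be risky to obtain. Cerebrospinal fluid (CSF) collected during
routine ventricular drainage carries tumor-derived cfDNA whose methylation
profile is entity-specific, so a reduced-representation bisulfite assay on a
few nanograms of CSF cfDNA can, in principle, classify the tumor without
surgery. `cfdeconv` implements the computational half of that workflow for
anyone working with low-input cfDNA methylation data:

1. **Reference atlas** — MspI fragments of the assay are intersected with
   methylation-array probes; per-sample probe betas are summarized to a
   cluster-level matrix **A** (one column per reference sample, entity
   labelled, tumoral/non-tumoral flagged), with healthy-cfDNA and
   white-blood-cell columns appended as the non-tumoral background.
2. **Quantification** — per-CpG calls (Bismark coverage format) become a
   per-cluster observation vector **b** (median of per-CpG betas), alongside
   QC metrics: cfDNA fraction of total DNA mass (fragments of 70–700 bp vs
   high-molecular-weight DNA above 700 bp) and bisulfite conversion rate
   from an unmethylated lambda spike-in.
3. **Deconvolution** — solve min ‖Ax − b‖₂ s.t. x ≥ 0 (NNLS), normalize
   x to relative contributions, aggregate columns to entities. The
   *estimated tumor fraction* (ETF) is the summed tumoral weight; the
   predicted entity is the tumoral argmax (non-tumoral signal never drives
   the call).
4. **Confidence gate** — a classification is flagged confident only when
   cfDNA fraction ≥ 0.40 **and** ETF ≥ 0.30 (inclusive, configurable).
5. **CNV profiling** — read counts in 400-kb bins, scaled to a common
   autosomal total and normalized against a panel of normals (per-bin
   median/MAD), with gain/loss segments called from runs of |z| > 3.

A fully seeded synthetic-data module generates atlases, binomially sampled
mixtures, fragment-length profiles and CNV bin counts with known ground
truth, so every stage is testable without access-controlled patient data.

## Worked example

```python
import numpy as np
from cfdeconv import (MethylationDeconvolver, cfdna_fraction,
                      confidence_gate, simulate_atlas)
from cfdeconv.simulate import (region_counts_to_beta_vector,
                               simulate_fragment_profile, simulate_sample)

# ground-truth reference: 4 tumor entities + healthy cfDNA + WBC
atlas = simulate_atlas(n_entities=6, n_regions=1000, markers_per_entity=30,
                       margin=0.5, seed=1)

# a sample: 45% tumor (TUM02), 35% healthy cfDNA, 20% WBC, coverage 30x
weights = {e: 0.0 for e in atlas.entities}
weights.update({"TUM02": 0.45, "healthy_cfDNA": 0.35, "WBC": 0.20})
counts = simulate_sample(atlas, weights, mean_coverage=30, seed=2)
sample = region_counts_to_beta_vector(counts, atlas, "patient01")

est = MethylationDeconvolver.from_atlas(atlas.to_reference_atlas())
res = est.deconvolve(sample)
profile = simulate_fragment_profile(cfdna_mass=6.5, hmw_mass=3.5, seed=2)
cf = cfdna_fraction(profile)
gate = confidence_gate(cf, res.etf)

print(f"predicted entity : {res.predicted_entity}")
print(f"ETF              : {res.etf:.3f}")
print(f"cfDNA fraction   : {cf:.3f}")
print(f"gate             : {gate.status}")
print(f"clusters used    : {res.n_clusters_used}")
```

Output:

```
predicted entity : TUM02
ETF              : 0.453
cfDNA fraction   : 0.650
gate             : confident
clusters used    : 1000
```

The deconvolution recovers the simulated 45% tumor weight as ETF 0.453 and
identifies the correct entity; with 65% of DNA mass in the 70–700 bp cfDNA
window and ETF above 0.30, the call passes the confidence gate.

`MethylationDeconvolver` and `PanelNormalizer` follow the scikit-learn
estimator conventions (`fit`/`transform`/`predict`, `get_params`, `clone`),
so they compose with sklearn tooling; module-level functions
(`nnls_deconvolve`, `normalize_against_panel`, …) wrap them for one-shot use.

## Command line

```bash
cfdeconv simulate  --config configs/default.yaml --outdir data/
cfdeconv run-all   --config run.yaml --outdir results/
```

`run-all` executes quantify → deconvolve → classify (plus CNV when bin
counts are listed) for every row of the samples manifest and writes
per-sample JSON reports plus a cohort summary stratified by gate status.
Subcommands `build-atlas`, `quantify`, `deconvolve`, `classify` and `cnv`
expose the individual stages; all randomness flows from the config seed.

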