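# germscreen

Comparative time-course metabolomics screening of seed-germination-associated
metabolites.

Seed germination is a fast metabolic transition: within the first 48 hours
after imbibition (HAI) a quiescent seed remobilizes nitrogen reserves, burns
storage lipids and switches on secondary metabolism.  When two varieties of a
crop germinate at different speeds — for example a fast *indica* and a slow
*japonica* rice — the metabolites whose trajectories track that difference are
prime candidates for regulators of germination.  `germscreen` implements, as a
tested and reusable pipeline, the screening strategy used in comparative
germination metabolomics:

1. **Replicate QC** — each replicate's metabolite vector is correlated against
   its siblings at the same variety × time point; discordant replicates
   (mean sibling PCC < 0.9 by default) are reported and optionally dropped.
2. **Stage segmentation and lag estimation** — the Pearson correlation matrix
   between variety × time-point profiles is segmented, per variety, into `k`
   contiguous developmental stages by an order-constrained agglomerative
   merge, and the slow variety's lag is read from best-matching time-point
   profiles.
3. **Three parallel candidate filters**
   - **COR**: Pearson correlation of a metabolite's 6–48 HAI replicate-mean
     content with germination rate; pass when `p < 0.05` and `|r| > 0.8`,
     with `p` from the classical transform `t = r·√(n−2)/√(1−r²)`, `df = n−2`;
   - **CV**: coefficient of variation `σ/μ` of the per-time-point means
     exceeds 30% — the metabolite's level actually fluctuates during
     germination;
   - **DAM**: differential accumulation between varieties at some tested time
     point — fold change of replicate means > 2 with a Benjamini–Hochberg
     adjusted two-sample Student's *t*-test `p < 0.05` (adjusted within each
     time point).
4. **Intersection** — COR ∩ CV ∩ DAM is the candidate set, broken down by
   compound class.
5. **Trajectory patterns** — candidate time courses are z-score standardized
   and classified into accumulation / consumption / accumulation-then-
   consumption / consumption-then-accumulation / flat via Spearman rank
   correlation with time plus an interior-extremum prominence rule.
6. **Module annotation** — candidates are matched (exactly, after name
   normalization) against two bundled germination modules: the
   ornithine–asparagine–polyamine (nitrogen-flow) module and the
   shikimate–aromatic–flavonoid (antioxidation/defense) module, with
   per-module direction-consistency counts.

Because real germination metabolome matrices are rarely redistributable, the
package ships a first-class synthetic-data generator (`germscreen.synthetic`)
that emulates the study design — 2 varieties × 8 time points
(0, 3, 6, 9, 12, 24, 36, 48 HAI) × 3 replicates, logistic germination curves
with a 6–12 h lag for the slow variety, planted germination-associated
metabolites, trajectory archetypes, multiplicative log-normal replicate noise
and optional outlier replicates — and emits the planted ground truth so every
stage of the screen can be validated end to end.

## Worked example

```python
from germscreen import RunConfig, SyntheticConfig, run_pipeline

cfg = RunConfig(simulate=SyntheticConfig(rng_seed=1), outdir="demo")
report = run_pipeline(cfg)
print(report["screen_counts"])
print(report["truth_confusion"])
```

prints (deterministically, for this seed):

```
{'cor_per_variety': {'fast': 127, 'slow': 143}, 'cv_per_variety': {'fast': 64,
 'slow': 66}, 'cor': 167, 'cv': 70, 'dam': 55, 'n_edges_passing': 270,
 'candidates': 55}
{'tp': 55, 'fp': 0, 'fn': 5, 'tn': 340, 'sensitivity': 0.9166666666666666,
 'precision': 1.0}
```

Of 400 simulated metabolites, 167 pass the correlation filter in at least one
variety, 70 the CV filter and 55 the differential-accumulation filter; their
intersection (55 candidates) recovers 55 of the 60 planted
germination-associated metabolites (sensitivity 0.92) with no false
positives.  The same run writes the QC report, profile-correlation matrix,
stage table, per-method sets, candidate table, z-score pattern table, module
annotation, and Cytoscape-loadable network files (CSV edge/node tables plus
GraphML and SIF mirrors) under `demo/`.

The same pipeline runs from the shell:

```bash
germscreen simulate --seed 1 --out sim/
germscreen run --simulate-seed 1 --outdir demo/
germscreen screen --metabolome sim/metabolome.csv --phenotype sim/phenotype.csv
```

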