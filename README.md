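# cfpipe

Computational companion to a cfDNA (cell-free DNA) protocol-optimization
workflow for prostate cancer liquid biopsies. Plasma cfDNA is fragmented at
nucleosomal sizes (~167/~340/~510 bp); its yield, purity, and tumor-derived
content carry clinical signal, but every downstream conclusion depends on
how the sample was purified, how much was sequenced, and how deep. `cfpipe`
implements the analysis layer of that workflow as a tested, reusable
library:

- **Electropherogram quantification** — trapezoidal integration of
  Bioanalyzer-style size-vs-density traces into the standard windows
  (50–250, 250–350, 350–550, 550–5000, >5000 bp); cfDNA concentration as
  the 50–550 bp mass summed over four column eluates, per mL plasma;
  per-eluate elution-recovery fractions; gDNA-contamination calls
  (>50 pg/µL of >5000 bp fragments, strict) and Qubit-minus-Bioanalyzer
  gDNA estimates.
- **Cohort statistics** — Wilcoxon rank-sum (exact enumeration at pooled
  n ≤ 12, midranks for ties; tie- and continuity-corrected normal
  approximation otherwise), Pearson correlation, Kaplan–Meier curves with
  log-rank tests, per-group median/range summaries, and an explicit 3×IQR
  outlier rule.
- **Consensus somatic-variant filtering** — four caller VCFs (Mutect2,
  VarDict, VarScan, Strelka2 conventions: single-sample, FORMAT `DP`/`AD`)
  merged on normalized variant keys and gated by five criteria: ≥2 callers,
  depth ≥10×, VAF ≥5% (recomputed as alt/depth from the deepest caller),
  ≥8 alt reads with 0 in matched germline, population allele frequency
  <0.01%, plus exclusion of benign/likely-benign annotations. Every
  candidate is kept in an audit table with per-criterion booleans.
- **Depth titration** — the compounded 20%-reduction downsampling schedule
  (147× → 117/94/75/60×), binomial/hypergeometric count thinning, and exact
  binomial detectability: P[≥ 8 supporting reads] as a function of depth
  and VAF, and the minimum depth achieving a target detection probability.
- **Tumor fraction and CNV clonality** — a transparent stand-in for
  HMM-based callers: tumor/normal log2 bin ratios, binary segmentation with
  merge and boundary-refinement passes, and a grid fit of tumor fraction TF
  with per-segment copy number c and cellular prevalence φ under the
  mixture model `log2R = log2((TF·φ·c + TF·(1−φ)·2 + (1−TF)·2)/2)`,
  with clonal-preferred parsimony and cross-depth concordance scoring
  (clonal concordance, false/missed subclonal events, clonality swaps).
- **Synthetic data** — seeded generators for every input above with known
  ground truth: nucleosomal trace ladders with optional gDNA contamination,
  a four-group clinical cohort (healthy / radical prostatectomy /
  disease-free / mCRPC) calibrated to published medians including the
  negative size–concentration correlation in mCRPC, four-caller callsets
  with caller-specific false positives and germline contaminants, and
  binned read-count profiles with clonal and subclonal segments at a
  chosen tumor fraction.

## Worked example

An end-to-end demo on synthetic data (seed 0):

```bash
cfpipe run --seed 0 --out demo/
```

prints, among other things:

```
"quantify": {
  "cfdna_ng_per_ml_plasma": 22.217454306229754,
  "first_elution_pct": 81.99999999999999,
  "purity": "pure"
},
"titration": { "depths": [117, 94, 75, 60], "n_detected_at_lowest": 0 },
"cnv": { "tumor_fraction": 0.25, "frac_genome_subclonal": 0.052, ... }
```

Reading this: 80 ng of simulated cfDNA from 3.6 mL plasma quantifies to
22.2 ng/mL; 82% of the mass elutes in the first of four elution steps; no
>5000 bp contamination, so the sample is called pure. The downsampling
schedule reproduces 117/94/75/60× from 147×, and none of the four true
variants (VAFs 6–10%) keeps ≥8 supporting reads at 60× — low-VAF variants
need deep coverage. The CNV stage recovers the simulated tumor fraction of
0.25 with ~5% of the genome in subclonal states.

The same stages are importable as a library (`cfpipe.electropherogram`,
`cfpipe.cohort`, `cfpipe.consensus`, `cfpipe.titration`, `cfpipe.cnv`,
`cfpipe.simulate`) and as standalone CLI subcommands (`simulate`,
`quantify`, `cohort-stats`, `filter-variants`, `titrate`, `cnv`).

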