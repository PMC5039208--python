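# triplenet

Triple-network analysis of resting-state fMRI: within-network functional
connectivity of the central executive (CEN), default mode (DMN) and
salience (SN) networks via group ICA and voxelwise statistics, and the
directed (effective) connectivity among them via a linear-Gaussian
Bayesian network selected by BIC, with between-group comparison of edge
weights by a group-label permutation test.

The package is aimed at methods work on small two-group cohorts (for
example, populations at elevated risk of neurodegenerative disease versus
controls): because such scanner datasets are rarely shareable, `triplenet`
ships a first-class synthetic cohort generator that plants known spatial
networks and a known directed model, so every stage of the analysis can be
validated by recovery of the planted truth.

## The model

Each subject's BOLD signal is treated as a spatial mixture
`y(v,t) = Σ_k s_g(k) M_k(v) x_k(t) + b·t + ε(v,t)`; group ICA
(per-subject temporal PCA → concatenation → second PCA → Extended
Infomax, with GICA back-reconstruction) recovers the spatial maps `M_k`
and per-subject versions of them. One-sample t-maps (Bonferroni FWE,
p < 0.001) define each network's ROI; two-sample t-maps (Benjamini–
Hochberg FDR, p < 0.05) locate within-network group differences.

Network-average time series then feed a Gaussian Bayesian network: each
node is linear-Gaussian in its parents, structures are scored by the
maximized BIC

    BIC(G) = Σ_j log L_j(θ̂_j) − (d/2) ln N ,

and the best structure is found exhaustively (all 25 three-node DAGs) or
by an L1-regularization-paths search. BIC is score-equivalent, so the
result is reported as a Markov equivalence class (CPDAG) with MLE edge
weights. Group differences in edge weights are tested by permuting
subject labels, relearning both group networks per permutation, and
computing empirical two-sided p-values with the add-one correction.

## Worked example

```python
import dataclasses, tempfile
from triplenet import PipelineConfig, run_pipeline

config = PipelineConfig(out_dir=tempfile.mkdtemp(), seed=1,
                        n_permutations=1000)
manifest = run_pipeline(config)   # ~1-2 minutes on one CPU
print(open(config.out_dir + "/report.md").read())
```

The default configuration simulates the emulated study design — 17
high-risk and 12 low-risk subjects, 120 time points, three planted
networks with a salience hub (SN→CEN 0.6, SN→DMN 0.5) and a 1.5× DMN
loading in the high-risk group — and the report ends with output like:

```
## Effective connectivity (per-group Bayesian networks)

### group HR (BIC -7823.21)
- DMN -> SN: weight 0.445
- SN -> CEN: weight 0.524
  ...
  - note: 3 BIC-tied structures; the BIC is score-equivalent over the
    Markov equivalence class, so reversible edges (CEN-SN, DMN-SN) are
    not identifiable from the data alone.

## Permutation test of edge-weight differences

- DMN -> SN: observed diff -0.015, p = 0.6044 (1000 permutations)
- SN -> CEN: observed diff +0.021, p = 0.3846 (1000 permutations)

No edge flagged at p <= 0.05.
```

Reading: both groups recover the planted salience-hub equivalence class
(skeleton SN–CEN, SN–DMN, no collider — the hub's orientation is not
identifiable from Gaussian BIC, and the report says so rather than
guessing), the weights are the planted values on the standardized scale,
and the permutation test correctly finds no group difference because none
was planted on the edges. The `stats/` directory holds the FWE network
masks (which overlap the planted spheres at Dice ≈ 0.6) and the FDR
two-sample map, which localizes the planted DMN loading difference
(HR > LR cluster, Dice ≈ 0.8 against the planted DMN mask).

The same stages are available from the shell:

```bash
triplenet simulate --out cohort/ --seed 1
triplenet preprocess --in cohort/ --out pre/ --discard 5 --fwhm 8
triplenet gica --in pre/ --out ica/ --order auto --seed 1
triplenet run --config examples/pipeline.yaml   # end-to-end with a manifest
```

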