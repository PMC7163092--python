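# irgpsig — immune-related gene-pair prognostic signatures

`irgpsig` builds and evaluates **gene-pair prognostic signatures** for
survival cohorts, the rank-based approach used for immune-related gene
pairs (IRGPs) in hepatocellular carcinoma.  Instead of using expression
levels directly, every feature is a within-sample comparison of two genes:

```
s_k(patient) = 1  if expr(gene_a_k) > expr(gene_b_k)  else 0
```

Because each indicator depends only on the ordering of two genes *inside
one sample*, the features — and everything downstream of them — are
invariant to any monotone per-sample transformation (log, scaling,
per-platform affine drift).  Signatures built this way transfer across
RNA-seq and microarray platforms without normalization or batch
correction, which is the method's core appeal.

The pipeline, aimed at statistical/bioinformatics researchers working with
expression + overall-survival data, is:

1. **Pair construction** — intersect cohort gene lists with an immune gene
   list, enumerate all C(n,2) unordered pairs, score indicators per sample.
2. **Prevalence filter** — discard pairs whose indicator is the same value
   in more than 90% of samples of either split (near-constant features).
3. **Prescreen** — per-pair two-group log-rank test on the training split,
   Benjamini–Hochberg FDR < 0.01.
4. **Model selection** — L1-penalized Cox regression
   `min  NLL(β)/n + λ‖β‖₁` with 10-fold cross-validated λ, repeated many
   times (1000 by default) with fresh random folds; the modal support size
   across iterations picks the final model, refit at the median selected λ.
5. **Risk stratification** — risk score `Σ_k β_k s_k`, median split into
   high/low risk, Kaplan–Meier + log-rank + (multivariable) Cox evaluation.
6. **Evaluation** — Harrell's c-index and KM-weighted cumulative/dynamic
   time-dependent ROC/AUC at 1/3/5-year horizons.

A 33-pair, 54-gene hepatocellular carcinoma signature is packaged as a
ready-to-use fixture (`irgpsig.load_packaged_signature()`), and a
synthetic-cohort generator with *planted* pair effects makes the entire
pipeline testable end to end with known ground truth.

## Worked example

Simulate a 40-gene, 400-patient cohort with three planted pairs
(log-hazard ratios +1.5, +1.5, −1.5), then run discovery:

```python
from irgpsig import SimulationConfig, simulate_cohort, RunConfig, run_discovery
from irgpsig.io_formats import write_expression_table, write_clinical_table

cfg = SimulationConfig(n_genes=40, n_patients=400,
                       planted_betas=(1.5, 1.5, -1.5), seed=4)
expr, cohort, truth = simulate_cohort(cfg)
write_expression_table(expr, "expression.tsv")
write_clinical_table(cohort, "clinical.tsv")
print("planted:", [str(p) for p in truth.planted_pairs])

config = RunConfig(expression="expression.tsv", clinical="clinical.tsv",
                   outdir="run", iterations=100, seed=1)
signature, reports = run_discovery(config)
for pair, coef in zip(signature.pairs, signature.coefficients):
    print(f"{pair}  {coef:+.3f}")
tr = reports["train"]
print(f"train: n={tr['n']} HR={tr['hazard_ratio']:.2f} "
      f"log-rank p={tr['logrank_p']:.2e} c-index={tr['c_index']:.3f} "
      f"AUC36m={tr['auc_36m']:.3f}")
```

Output:

```
planted: ['G0002>G0039', 'G0000>G0003', 'G0013>G0033']
G0000>G0003  +1.075
G0002>G0039  +0.874
G0000>G0009  +0.094
G0000>G0005  +0.092
G0003>G0011  -0.216
G0000>G0013  +0.213
G0031>G0039  +0.185
G0003>G0036  -0.139
train: n=219 HR=6.10 log-rank p=3.79e-12 c-index=0.791 AUC36m=0.900
```

Two of the three planted pairs are recovered with the correct signs; the
smaller-coefficient extras are "shadow" pairs sharing a gene with a planted
pair (their indicators are correlated with the true signal — the same
phenomenon that makes real signatures contain correlated partners).  The
high-risk half of the training cohort dies about 6× faster than the
low-risk half, and a 36-month AUC of 0.90 reflects the planted effect
sizes.  A pair name like `G0000>G0003` reads "score 1 when the first gene
is expressed above the second".

The same steps are available from the shell:

```bash
irgp simulate --n-genes 40 --n-patients 400 --betas 1.5,1.5,-1.5 --seed 4 --outdir sim
irgp discover --config run.cfg        # key = value file, see docs/methods.md
irgp validate --config val.cfg --signature run/signature.tsv
```

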