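# cpmconn

Connectome-based predictive modelling (CPM) of behavioural symptom
severity from whole-brain resting-state functional connectivity, with
multisite harmonization, permutation inference, independent-sample
validation, and network-anatomy summaries.

## The problem

Clinical neuroimaging studies increasingly ask whether a patient's
symptom severity — for example an autism severity score such as the ADOS
total — can be predicted from the individual functional connectome: the
matrix of correlations between regional resting-state fMRI time courses.
CPM is the standard data-driven protocol for this question. Data pooled
from many scanning sites carry scanner-specific offsets and scale
distortions on every connectivity edge, and head motion, age and sex
confound any naive brain–behaviour correlation, so the protocol has to
combine harmonization, covariate adjustment, and strict cross-validation
hygiene. `cpmconn` packages that whole chain as a tested Python library.

## The method

For subjects with Fisher-z connectomes `z_s` (edges `x_e`, the
`N(N−1)/2` upper-triangle entries), behaviour `y`, and covariates `C`
(age, sex, mean framewise displacement):

1. **Connectomes** — `z_ij = atanh(r_ij)` from Pearson correlations of
   node time courses (`|r| = 1` clipped to `1 − 1e−7`).
2. **Harmonization** — ComBat: per-site, per-edge location/scale effects
   estimated under the model `x = α + Cβ + γ_site + δ_site·ε`, shrunk by
   empirical Bayes (parametric or nonparametric prior) and removed;
   covariate-associated variance is restored.
3. **Edge selection** — partial correlation `r_e = corr(x_e, y | C)`;
   edges with two-sided `p < 0.01` form the positive (`r_e > 0`) and
   negative (`r_e < 0`) networks.
4. **Network strength** — `S_s = Σ_{e ∈ network} z_s[e]`, one sum per
   tail per subject.
5. **Prediction** — OLS `y = b₁·S + b₀`, one single-predictor model per
   tail, under leave-one-out cross-validation: selection and fit use
   `n − 1` subjects, the held-out subject is predicted, and edges
   retained in *every* fold form the consensus network.
6. **Evaluation** — partial correlation (given `C`) between pooled
   held-out predictions and observed scores; significance from 1000
   (configurable) shuffles of `y` with the full LOOCV re-run each time,
   `p = (1 + #{r_null ≥ r_obs}) / (1 + n_perm)`.
7. **Transfer** — the consensus network plus a full-sample refit of the
   tail model are applied unchanged to an independent patient sample
   (replication) and to healthy controls (specificity, expected null);
   Benjamini–Hochberg FDR within each sample's family of tests.
8. **Anatomy** — node degree and K×K within/between-network connection
   counts against an atlas (the bundled 160-node, six-network functional
   parcellation or any atlas CSV).

A built-in synthetic-data generator emulates the full study design —
model/validation/control samples, confounded covariates, per-site edge
effects, and a sparse planted edge set coupled negatively to behaviour —
so every stage is testable by recovery of known ground truth.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_cpm_loocv.py` (an 80-subject, 30-node planted study)
prints:

```
neg network: r(df=75) = +0.959  p_perm = 0.0050  mean null r = -0.071  consensus edges = 10
pos network: r(df=75) = -0.169  p_perm = 0.6468  mean null r = -0.084  consensus edges = 1

planted negative edges recovered: 10 / 10
```

The negative network recovers all ten planted edges and predicts the
held-out scores almost perfectly (`r` is the covariate-adjusted
correlation between LOOCV predictions and observed scores; `p_perm =
1/201` is the smallest value attainable with 200 shuffles). The positive
network, which carries no planted signal, stays at chance.
`python examples/05_validate_and_anatomy.py` then transfers that
network:

```
validation: n= 50  r=+0.976  p=0.0000
   control: n= 36  r=-0.190  p=0.2888
```

— significant replication in independent patients, a null result in
uncoupled controls — and prints the degree table and six-network
connection-count matrix of the consensus network.

The full study replica (simulate → filter → harmonize → CPM per score
and subtype → validate → anatomy) runs from one YAML config:

```bash
cpmconn run --config run.yaml --out results/run1
```

or programmatically via `cpmconn.run_pipeline(RunConfig(...), out_dir)`.

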