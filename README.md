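# turnpoint

Statistical analysis of time-resolved, two-layer omics data: detect
time-specific changes in synthesis/degradation kinetics with change-point
probability scores (CPS) and Bayesian FDR control, estimate per-interval
synthesis and degradation rates from pulsed-label or generic protein data,
smooth and impute rugged series with a Gaussian process, boost detection
with a network (MRF) prior, and summarize regulation per biological
function per time point.

## Modules

| module               | purpose |
|----------------------|---------|
| `turnpoint.io`       | tab-delimited expression matrices, edge lists, GMT gene sets, result tables; validated domain types (`TimeGrid`, `ExpressionSeries`, `PairedDataset`, `Network`, `GeneSetCollection`) |
| `turnpoint.gp`       | per-gene/replicate Gaussian-process smoothing and imputation (squared-exponential kernel, shared hyperparameters, marginal-likelihood tuning) |
| `turnpoint.core`     | Bayesian change-point inference on synthesis/degradation **rate ratios** from a paired template–product dataset; CPS per gene per interior time point; pooled Bayesian FDR map |
| `turnpoint.network`  | the core model with a Markov-random-field change prior over a user-supplied gene network (signed neighbor concordance) |
| `turnpoint.pulsed`   | per-interval synthesis and degradation rates from pulsed-label H (new, rising) and M (pre-existing, falling) channels; monotonicity filter; separate CPS per rate |
| `turnpoint.rates`    | synthesis/degradation deconvolution from generic (non-pulsed) paired data under the identifiability restriction (increases → synthesis, decreases → degradation, unless template-explained) |
| `turnpoint.gsa`      | exact hypergeometric gene-set enrichment per time point and direction; signed −log10 p heatmap export |
| `turnpoint.simulate` | synthetic paired/pulsed/total datasets with known ground-truth rates and change points |
| `turnpoint.cli`      | `turnpoint` command-line pipeline (simulate → gp → model → gsa) |

## Command line

```bash
# make a synthetic paired dataset with known truth
turnpoint simulate --preset core --n-genes 200 --seed 1 --out sim/

# smooth + impute (optional; models tolerate noise but smoothing helps)
turnpoint gp --input sim/protein.tsv --layout 8x2 --times 0,1,2,3,4,5,6,7 \
    --auto-hp --out gp_out/

# rate-ratio change points (protein level: protein paired with mRNA)
turnpoint core --mrna sim/mrna.tsv --protein sim/protein.tsv \
    --layout 8x2 --times 0,1,2,3,4,5,6,7 --seed 1 --out core_out/

# RNA-level regulation: mRNA paired with a constant unit template
turnpoint core --mrna sim/mrna.tsv --rna-only --layout 8x2 \
    --times 0,1,2,3,4,5,6,7 --seed 1 --out rna_out/

# network prior / pulsed channels / generic-data rate deconvolution
turnpoint net ... --network edges.tsv --estimate-beta
turnpoint ps --heavy heavy.tsv --medium medium.tsv --mrna mrna.tsv ...
turnpoint r --mrna mrna.tsv --protein protein.tsv ...

# time-resolved gene-set enrichment on a CPS table
turnpoint gsa --cps core_out/cps.tsv --gmt sets.gmt --fdr 0.05 --out gsa_out/

# or drive the whole pipeline from a YAML config
turnpoint run --config config.yaml
```

Example `config.yaml`:

```yaml
seed: 1
times: [0, 0.5, 1, 2, 8, 16, 24, 30]
layout: {n_reps: 2}
inputs: {mrna: mrna.tsv, protein: protein.tsv}
gp: {enabled: true, auto_hp: true}
model: {kind: core, n_iter: 4000, n_burn: 2000, thin: 2, target_fdr: 0.05}
gsa: {gmt: sets.gmt, min_k: 3, size_range: [5, 500]}
out_dir: results/
```

Inputs are tab-delimited: first column gene id, remaining columns the
time × replicate layout (time-major by default, `--layout TxR`). Empty
cells, `NA` and `NaN` are missing; genes with more than 2 missing time
points in any replicate are excluded (configurable). Edge lists are 2–3
column TSV (optional STRING-style 0–1000 score, `--min-score`); gene sets
are standard GMT. All outputs are tab-delimited with `#` header comments
recording the package version and a config hash; identical config + seed
reproduce outputs bit-identically.

## Model sketch

Product dynamics follow the interval mass-action update
`E[Y_{t+1}] = E[Y_t] + Δh_t (κ_s,t X_t − κ_d,t E[Y_t])`. The core model
infers the ratio `r_t = κ_s,t/κ_d,t` (only the ratio is identifiable from
paired data) with piecewise-constant log-rates between change points;
`CPS_gt` is the posterior probability of a change indicator at each
interior time point, with a per-time-point change prior shared across
genes (replaced by the network-coupled prior in `turnpoint.network`). The
pulsed model reads synthesis from the rising new-protein channel
(`ΔH = Δh κ_s X`) and degradation from the decaying pre-existing channel
(`M_{t+1} = M_t e^{−κ_d Δh}`). The generic-data model frees both rates but
restricts the parameter space by attributing each concentration change
(synthesis-driven, degradation-driven, template-driven, or none). Rates
are relative ("up to a constant"); all observation noise is Gaussian on
log10 intensities with heavy-tail (Student-t) robustness.

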