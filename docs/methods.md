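# Methods

## The model

`pharmspace` predicts how a tumor — resolved into transcriptomically
distinct cell clusters — responds to single drugs and drug pairs, using
only a cell-line drug screen for training and a single-cell expression
matrix (plus external cluster labels) for the query.

### Sensitivity scale

All drug response lives on the scale s = −log2(IC50 µM): one unit is a
two-fold change in concentration and larger s means more sensitive.
Each drug carries its maximum tested dosage on the same scale,
o = −log2(max dose µM). A sample is *sensitive* to a drug when its IC50
is below the maximum tested dosage, i.e. s > o; an IC50 beyond the tested
range is an extrapolation of the fitted viability curve and is treated as
unreliable.

### Kernel features

A sample (cell line, cell, cluster mean, or pseudo-bulk) is featurized as
x_u ∈ R^d: the Pearson correlations between its per-gene log-expression
fold-change (relative to the mean over the d training cell lines,
restricted to an essential-gene panel) and the fold-change of each
training line. The reference means and fold-changes are frozen at fit
time, so a single unseen sample featurizes identically whether it arrives
alone or in a batch. TPM-scale query profiles are bridged to log scale as
log2(TPM+1) before fold-change (configurable). Correlations use the
intersection of essential genes present on both sides (minimum 2, warning
below 50% coverage) since dropout guarantees partial overlap in
single-cell data.

### The factorization and its calibrated objective

Predicted sensitivity is

    ŝ_iu = b_i^Q + q_i · (x_u W_P),

with W_P ∈ R^{d×f} projecting kernel features into an f-dimensional
latent space shared by drug vectors q_i. There is no global mean or
per-sample bias: an unseen sample's bias cannot be estimated, so it is
absorbed into the projection. Training minimizes

    L = (1/2K) [ Σ_{(i,u) observed} d_u c_iu (s_iu − ŝ_iu)² + λ(‖Q‖² + ‖W_P‖²) ],

where K counts observed pairs, d_u ≥ 1 optionally up-weights samples of a
focus cancer type (d_u = 10 for indication-specific models), and

    c_iu = min( σ(l(s_iu − o_i)), σ(l(ŝ_iu − o_i)) )

with σ the logistic function. When both the observed and predicted IC50
lie beyond the maximum tested dosage both sigmoids are small, so errors
against extrapolated IC50s are suppressed; pairs on the sensitive side
keep full weight. The min (rather than a product) means one reliable side
cannot rescue a pair the other side flags as extrapolated.

### Training

Plain full-batch gradient descent (learning rate 0.01, at most 100,000
epochs; Adam is available in the config but not the default). The
calibration weights c_iu are recomputed from the current predictions at
the start of each epoch and held constant inside the epoch's gradient:
differentiating through c would reward pushing every prediction deeply
insensitive, a degenerate descent direction. W_P and Q start at
Gaussian(0, 0.01); b_Q starts at each drug's weighted mean observed
score, its closed-form optimum for the zero-latent model. L2 applies to
Q and W_P only (λ = 0.01 by default) — penalizing b_Q would distort
per-drug baselines. Early stopping triggers when the relative loss change
over a 100-epoch window drops below `tol` (default 1e-7; the acceptance
runs use 1e-9). Training is deterministic given the config.

### Evaluation

Five-fold cross-validation holds out each fold's samples entirely
(expression and response). Accuracy is the fraction of observed pairs
whose predicted class (s > o) matches the observed class; the boundary
IC50 = max dose is classed insensitive (strict inequality for
sensitivity). The error metric is the *median* absolute error of
ŝ over pairs whose **observed** class is sensitive — conditioning on the
observed label keeps the metric independent of the classifier being
scored, and sensitive pairs are the ones whose IC50s are interpolated
rather than extrapolated.

### Dose-response aggregation

Each unit's curve is a two-parameter logistic in log2 dose with fixed
0%/100% asymptotes: death(x) = 1/(1 + 2^{b(m − x)}), m = log2(IC50 µM),
slope b = 1 by default (m = −ŝ for model predictions). A patient is a
weighted mixture of clones; its combined kill at dose x is the weighted
average of clone curves. The combined IC50 solves
Σ_k w_k death_k(x) = 1/2, found by Newton iteration started at the naive
weighted average of the clone m_k (log-space averaging keeps the
initializer inside the bracket and scale-equivariant). Because the
mixture kill is strictly increasing, the root is unique and lies in
[min m_k, max m_k]; any Newton step that leaves the maintained bracket or
fails to shrink the residual falls back to one bisection step, so
convergence is guaranteed. Kill fractions are clamped to
[1e−12, 1 − 1e−12] before derivatives. No slope is re-estimated for the
combined curve — when a full curve is needed the mixture kill is
evaluated directly.

### Heterogeneity score

ITTH (intra-tumor transcriptomic heterogeneity) is the Shannon entropy,
in nats, of a sample's cell-type or cluster composition after dropping
entries below 5% frequency and renormalizing the survivors (a proper
distribution keeps the entropy interpretable, and quartile-based
classification is invariant to the log base either way). Samples are classed low/medium/high by the
cohort's first and third quartiles (linear interpolation); scores exactly
at a quartile are "medium".

### Combinations

Two drugs at stated dosages act independently within a clone: combined
kill h_i + h_j − h_i h_j. Patient-level kill is the cluster-fraction
weighted average; a combination's utility is its improvement over the
better monotherapy, which is non-negative by construction. The screening
filter for candidate pairs (minimum per-drug cross-validation accuracy,
improvement in at least one patient) mirrors how combinations would be
shortlisted for experimental follow-up; both thresholds are arguments.

### Pathway association

Pathway activity of a sample is the sum of member-gene log2 fold-changes
(GMT input); drug-pathway association is the Pearson correlation between
activity and predicted kill fraction across training samples. Positive r
means high activity tracks sensitivity. No multiple-testing correction by
default (a Benjamini–Hochberg option exists) since the scores are used
for ranking and interpretation rather than hypothesis rejection.

## Synthetic data

`generate_panel` emulates a cell-line screen: latent positions
P ~ N(0, I_f) per line, expression emitted through shared gene loadings
(baseline + P·G/√f + N(0, 0.1) noise) so that expression correlation
reflects latent proximity — the premise that makes kernel features
informative; true sensitivity s = b_Q + Q Pᵀ with Q, b_Q ~ N(0, 1);
observed scores add N(0, σ) noise (default σ = 0.3) and are masked at a
10% missing rate; each drug's maximum dose sits at the median of its true
scores so both classes are populated. Defaults (60 lines, 8 drugs,
500 genes, f_true = 5) are the standard study conditions used throughout
the tests and the acceptance script.

Deliberate simplifications: expression noise is Gaussian on a log-like
scale (no count/dropout model — UMI-realism is out of scope), the
latent-to-expression map is linear, and drugs/lines are exchangeable.
Two consequences matter for interpreting results. First, Pearson kernel
features see only the *direction* of a line's latent position, not its
magnitude, so even a noiseless panel caps held-out correlation against
this truth around 0.9 — recovery numbers should be read against that
ceiling, not against 1. Second, passing these tests shows the machinery
is correct and calibrated under its own assumptions; it does not certify
accuracy on real tumors, where batch effects, non-linear structure and
dropout intervene.

`generate_heterogeneous_patient` builds a patient as clusters around
log-normal base profiles with clipped Gaussian noise and optional dropout
zeroing; truth composition (counts and base profiles) is returned.
`generate_mixture_curves` draws Dirichlet weights, IC50s uniform on
[−6, 6] log2 µM and slopes uniform on [0.5, 3] for the root-finding
checks.

## Numerical and design choices

- **Boundaries:** cells with exactly 10,000 reads and genes at exactly 5%
  prevalence are kept (removal criteria are strict inequalities);
  mitochondrial fraction ≥ 25% removes a cell; "expressed" means TPM > 0.
- **Units:** µM everywhere at ingest, log2 µM internally.
- **Duplicate gene rows** collapse to their mean with a warning.
- **Logistic slope** l = 1 per −log2-µM unit by default (configurable):
  the weight falls to ~0.01 five two-fold dilutions past the tested range.
- **Serialization** is a single JSON archive; floats survive bit-exactly
  via shortest-repr round-tripping, and repeated seeded runs produce
  byte-identical archives.
- **Problem sizes:** the test suite and acceptance script run the study
  conditions above (two 5-fold CVs at 60×8, plus 1,000-mixture and
  1,000-fixture property sweeps), which complete in a few minutes on one
  CPU.

## Known limitations

- Cluster labels are an input; no clustering, embedding, or
  highly-variable-gene selection is provided.
- Cell-type fractions for ITTH are an input; deconvolution is external.
- The independence model ignores pharmacological interaction (synergy or
  antagonism) and toxicity constraints.
- IC50 and slope inputs are taken as given; fitting viability curves from
  raw plate data is out of scope.
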