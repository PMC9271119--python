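# Methods

## The model

`wgnam` analyses plot-level trait data from a nested association mapping
(NAM) population — families of recombinant inbred lines (RILs), each family a
cross between a common reference parent and a diverse donor — in a single
linear mixed model:

    y = X tau + Z0 u0 + Zg u_g + eps

* `y` (length N) are the raw plot observations, not genotype means: the
  one-stage formulation keeps the genotype-mean uncertainty inside the model,
  which matters for partially replicated trials.
* `X tau` holds the intercept, fixed effects for check/standard entries, and
  (optionally) replicate as a fixed factor.
* `Z0 u0` are optional iid non-genetic random blocks (e.g. replicate).
* `eps ~ N(0, sigma2_e I)`; spatially correlated residuals are out of scope
  here (iid only).

The line-level genetic effect decomposes marker by marker through
founder-allele inheritance probabilities.  For line `i` and marker `j`,
`p_ij` is the length-`n_f` vector of probabilities that the line's allele
descends from each founder, and

    u_g[i] = sum_j p_ij' a_j + u_p[i]

with founder-effect vectors `a_j ~ N(0, sigma2_a I)` shared across all
markers not yet declared QTL, `a_j ~ N(0, sigma2_aj I)` with a private
variance for each selected QTL `j`, and an iid polygenic remainder
`u_p ~ N(0, sigma2_p I)`.  Probabilities rather than allele counts are what
let a single model span families with different parents: a founder absent
from a line's family simply has probability zero.

## Founder probabilities

`probs.compute_founder_probabilities` treats each marker independently and
compares the line's call with its two family parents: if the parents carry
different homozygous genotypes, a line matching a parent inherits that
parent's allele with probability 1, a heterozygous call gives 0.5/0.5; if
the parents share a genotype the marker is uninformative for that family and
every line gets 0.5/0.5 on the two parents.  Degenerate cases (missing
parent, line call inconsistent with both parents) fall back to the
uninformative 0.5/0.5 with a warning — quality control should have removed
such markers.  The QC filters are: within-family line missing rate > 0.5 in
any family, overall missing rate > 0.1, minor allele frequency < 0.01
(fixed markers included), and parent-conflict markers (both homozygote
classes above 5% within a family whose parents agree).  The 5% conflict
threshold is this package's reading of an approximate published figure.
Missing line calls are first imputed from the parents where both agree.

Externally computed probability files (e.g. from a multipoint hidden-Markov
method) are accepted as a long-format CSV; rows are renormalized when within
1e-6 of unit mass and mass on non-parent founders is warned about but kept,
since multipoint methods may legitimately spread mass.

## REML engine

All variance components are estimated by residual maximum likelihood.  The
naive parameterization has one random effect per founder x marker
(`n_f * n_m` ~ 5000 columns); the engine works instead in the `n_g`-dim
line space: the common term enters as the kernel

    K = c * sum_{j not in S} Q_j Q_j',    c = n_g / trace(sum Q_j Q_j')

with `Q_j` the n_g x n_f probability slab at marker j, and each selected QTL
as a rank-`n_f` kernel `Q_j Q_j'`.  The scaling `c` only conditions the
optimization: the reported likelihoods, LRT statistics, outlier statistics
and BLUPs are invariant to it (asserted by tests), and BLUPs are
back-transformed with `c` so effects live on the probability scale.

Writing variance ratios `gamma_k = sigma2_k / sigma2_e` and
`Gamma = sum_k gamma_k C_k`, the covariance is `V = sigma2_e (I_N + Zg Gamma
Zg')`.  `sigma2_e` is profiled out analytically and the profiled residual
log-likelihood is maximized by L-BFGS-B with analytic gradients over the
ratios, bounded below by zero.  Three exact evaluation strategies share one
interface:

* a spectral path when every observation has the same replicate count and
  the structure is polygenic +- one dense kernel (everything is diagonal in
  the kernel eigenbasis; one eigendecomposition per data set, O(n_g) per
  likelihood evaluation) — this carries the null-scenario simulation study;
* a general symmetric path through `A = I + M^(1/2) Gamma M^(1/2)`
  (`M = Zg'Zg`), with every quadratic form written as
  "within-line part + u'A^(-1)u" so that no catastrophic cancellation occurs
  even when ratios are enormous (near-noiseless data) and ratios may sit
  exactly on the zero boundary;
* a generic path when iid non-genetic blocks are present, which inverts the
  full block Gamma and therefore keeps ratios a hair above zero (1e-10).

Ratios below 1e-8 are reported as exact zeros.  Convergence uses tight
relative tolerances (ftol 1e-11, gtol 1e-7, max 100 iterations by default);
a stalled line search triggers one restart, and solutions are accepted when
the boundary-projected gradient is small.  Warm starts with extreme ratios
(degenerate, effectively noiseless data) additionally cross-check the
default start because the profiled surface is nearly flat there.  The
reported log-likelihood includes all constants, so values are comparable
across fits sharing the same fixed-effects design, and equal (to 1e-6) those
of an explicit dense-V fit — the test suite verifies this against
independent dense oracles, including Henderson mixed-model-equation BLUPs.

Rank-deficient fixed-effect designs drop trailing confounded columns with a
warning.

## The genome scan

Each iteration fits two models sharing the selected-QTL terms: *reduced*
(polygenic + selected QTL) and *complete* (+ the common kernel over the
remaining markers).  The likelihood-ratio statistic for the boundary
hypothesis `sigma2_a = 0` is referred to the mixture `0.5 chi2_0 +
0.5 chi2_1`; because only one whole-genome component is tested per
iteration, no multiple-testing correction is applied.  While `p <= alpha`
(default 0.05) the scan computes the outlier statistic for every remaining
marker from the complete fit's cached projector (a score-type computation —
no per-marker refits):

    t2_j = sum_l a~_jl^2 / sum_l var(a~_jl)

and moves the argmax marker into the selected set with its own variance
component.  Ties break to the smallest genome order; markers whose BLUP
variance vanishes (< 1e-12) score zero.  Termination reasons: p above
alpha, the common variance estimated at zero, or the iteration cap (default
40).  Only the selected marker leaves the common kernel — no exclusion
window around it.  The outlier statistics are computed from the complete
model's fit, the natural reading of the score construction for
not-yet-selected positions.  The final model is the last reduced fit
(polygenic + all selected QTL).

## Assessment of the final model

For each selected QTL the BLUP vector `a~_j` and its prediction error
variance `PEV_j` (with `Var(a~_j) + PEV_j = sigma2_aj I` by construction)
yield:

* an overall strength probability
  `p_j = P(chi2_nu > a~_j' PEV_j^+ a~_j)` with `nu = rank(PEV_j)`
  (eigenvalues above 1e-8 of the largest; Moore-Penrose pseudoinverse),
  exact under the model's normal conditional distribution, and
  `LOGP = -log10 p_j`;
* founder-specific probabilities `1 - Phi(|a~_jl| / se_jl)` from the PEV
  diagonal — a zero effect anchors at probability 0.5000, score 0.30.  The
  one-sided-normal form is inferred from that anchor; the original
  implementation does not publish its formula;
* the share of line-level genetic variance,
  `%var_j = 100 * Var_i(p_ij' a~_j) / Var_i(u~_g[i])`, an empirical
  decomposition (no closed formula is published); covariances between QTL
  contributions are absorbed in the denominator only, and the polygenic
  share is defined residually so the shares total 100.

Report tables list per-founder size/probability/score next to the overall
columns, and a thresholded summary keeps QTL with overall or founder score
above `-log10(0.05) = 1.30`, labelled "overall"/"specific".

## The simulator

The preset emulates the study conditions: a reference parent crossed to five
donors, five families x 100 fully inbred RILs, seven linkage groups
("1B"–"7B") of 895 markers total (per-group counts 140/120/110/130/145/123/
127, within the published 77–223 range), group lengths max(QTL position,
180) cM, and markers forced at the eight QTL positions.  Phenotypes follow
`y_ir = mu + sum_jl p_ijl a_jl + u_i + e_ir` with mu = 7,
`u ~ N(0, 0.5)`, `e ~ N(0, 1)`, two replicates; the null scenario drops the
QTL sum.  The eight-QTL architecture (founder order Suntop, SeriM82,
ZWB10.37, Drysdale, Westonia, Dharwah dry):

| QTL | LG | cM | effects |
|---|---|---|---|
| 1 | 1B | 94.39 | 0.4, -0.2, -0.2, 0, 0, 0 |
| 2 | 2B | 17.84 | 0.5, -0.1, -0.1, -0.1, -0.1, -0.1 |
| 3 | 3B | 19.00 | 0.4, 0, 0, -0.4, 0, 0 |
| 4 | 4B | 62.27 | 0, -0.6, 0, 0, 0, 0.6 |
| 5 | 5B | 60.11 | 0.2, 0, 0, -0.1, 0, -0.1 |
| 6 | 6B | 57.39 | 0.2, -0.04, -0.04, -0.04, -0.04, -0.04 |
| 7 | 7B | 101.51 | 0.2, 0, 0, 0, 0, -0.2 |
| 8 | 1B | 161.57 | 0, -0.3, 0, 0, 0.3, 0 |

Meioses use the Haldane map function (no interference),
`r = (1 - e^(-2d/100))/2`.  Fully inbred lines are drawn from the
RIL-by-selfing limit as a Markov chain along each linkage group with switch
probability `R = 2r/(1+2r)` between adjacent markers (the Haldane–Waddington
two-point law, which the tests verify empirically); finite selfing
generations simulate the meioses explicitly and leave residual
heterozygosity (0.5/0.5 truth rows).  Founder marker profiles are synthetic:
donor-vs-reference differences follow a two-state Markov chain along each
group with stationary difference frequency 0.4 and per-marker persistence
0.9 (blocks), and monomorphic columns are redrawn so every marker segregates
in at least one family.  The real genotyping-platform profiles are not
available; this block structure reproduces their qualitative feature
(contiguous identity segments) but not their exact information content, so
power results carry wider tolerance bands than type-I error.  Seeds: one
base seed; family, phenotype and per-study streams derive from it by fixed
offsets, making any subset bit-reproducible.

## Simulation studies

`run_null_study` and `run_power_study` regenerate the full bundle per
replicate (map, founders, RILs, phenotypes), run the complete forward
selection at alpha = 0.05, and classify each selected marker against the
true QTL: assigned to the nearest true QTL on the same linkage group within
10 cM (detection; multiple assignments count once), otherwise a false
positive.  Failed fits are excluded from rates and reported separately.

The probabilities handed to the scan default to the simulator's true founder
origins (`probability_source="multipoint"`).  This stands in for the
dense-map multipoint (HMM) IBD probabilities that the method is normally run
with in this protocol; at ~1.4 cM marker spacing with fully informative
flanking data those are numerically indistinguishable from the truth for
inbred lines.  The alternative `"single_marker"` source recomputes the cube
from the marker data with the parent-comparison rules; because that leaves
uninformative 0.5/0.5 rows wherever a family's parents agree at the marker,
it discards the information multipoint methods recover from neighbours and
detection power drops accordingly (roughly halved for QTL whose effects are
confined to a subset of families) — a useful illustration of why multipoint
probabilities are preferred in practice.

Effect-recovery summaries compare the scan's zero-centered founder
predictions with the true effect vectors after centering each per QTL.

Problem sizes in the shipped checks: the test suite runs the type-I study at
200 replicates and the power study at 24 replicates with Monte-Carlo
allowances folded into its statistical bands; `scripts/acceptance.py`
re-runs the type-I study from scratch at the full 500 replicates.

## Known limitations

* Residuals are iid: the spatially correlated field-trial models the method
  is used with in practice (AR1 x AR1) are not implemented.
* Founder relationship matrices (related founders) are not supported; founder
  effects are iid within a marker.
* The founder-replicate consistency filter only applies when multiple
  profile columns per founder are supplied.
* Single-marker probabilities are the only built-in computation; multipoint
  (map-based HMM) probabilities must be supplied externally, and in the
  generic-path (group random blocks) variance ratios cannot sit exactly at
  zero (bounded at 1e-10).
* Genotyping-error models and selection during population development are
  not simulated.
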