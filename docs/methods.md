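# Methods

## Synthetic study design

The generator emulates a time-series EMT perturbation study: 4 cell lines ×
3 signals, eight timepoints per condition (0, 8 h, 1 d, 3 d, 7 d of
induction; 8 h, 1 d, 3 d after removal), with the day-7 cells belonging to
both the forward and the backward dataset. Per condition each TF has a
temporal role: E (monotone decrease during induction, recovery after
removal), M (mirror image), I (rise by the effect size at intermediate
timepoints, then fall), I2 (mirror of I), or flat. Role mean trajectories
are fixed fractions of `effect_size` at the eight design timepoints
(piecewise-linear in log-time between them); the removal branch is
deliberately not the time-reverse of the induction branch, so forward and
backward paths form an open loop as hysteretic systems do.

Ground-truth circuits have a team structure: an E team and an M team with
intra-team activation cycles and inter-team mutual inhibition, I/I2 TFs
bridged between the teams, and flat TFs left unwired. Roles switch between
conditions at rate `role_switch_rate` (hierarchically when a cell-line ×
signal grid is requested: full rate between cell lines, a third of it
between signals of one line, so same-cell-line conditions share more roles
than same-signal ones). Every condition keeps at least 5 E/M TFs so the
downstream network screening is satisfiable; switches are reverted, rarest
first, when a draw would violate this.

Per-cell activities are the role mean plus homoscedastic Gaussian noise
(activities are continuous regulon-activity scores, not counts). Two
deliberate structural features matter downstream:

- **Edge coupling.** A signed, strength-weighted fraction
  (`edge_coupling`, default 0.9) of each regulator's intrinsic fluctuation
  is added to its true targets. Regulon-linked TF pairs therefore
  co-fluctuate within a timepoint, while decoy pairs correlate only through
  shared trajectory shapes — precisely the contrast the mutual-information
  scoring stage is supposed to exploit. Without within-timepoint coupling,
  trajectory-correlated decoys would be statistically indistinguishable
  from true edges.
- **Backward affine distortion.** Backward-direction measurements live on a
  per-TF affine scale (slope U[0.5, 2], intercept U[−1, 1]), emulating the
  two directions having been processed separately. The distortion is stored
  on the dataset and applied when the backward split is materialized
  (including its copy of the day-7 cells), which keeps cell ids unique in
  the combined dataset while giving the rescaling stage an exactly
  recoverable target: with a deterministic distortion the day-7 anchors are
  perfectly correlated across scales, so the per-TF least-squares fit
  inverts it to machine precision.

Defaults — 100 cells per timepoint, `noise_sd` 0.5, `effect_size` 2 (a
4:1 signal-to-noise ratio for driven TFs), regulon `decoy_rate` 0.3 with
10% per-direction dropout — are fixed once as a plausible strong-signal
regime; there is no public quantitative description of real activity
distributions to calibrate against. What the generator does *not* emulate:
UMI counting noise, dropout, cell-cycle or batch structure, regulon
inference errors beyond uniform decoys, or TF–TF correlations not mediated
by the circuit. Passing tests therefore demonstrate the pipeline's internal
consistency and recoverability under its own assumptions, not performance
on real scRNA-seq data.

## Differential activity

Tests are two-sided Wilcoxon rank-sum per TF (exact null for small tie-free
samples, tie-corrected normal approximation otherwise) with Bonferroni
adjustment over the TFs of each comparison and no fold-change pre-filter.
"Fold change" on activities is the difference of group means; only its sign
and significance are consumed. A TF *occurs* in a comparison when it is in
the top 100 by adjusted p *and* significant at 0.05 — the conservative
conjunction of the two published selection phrasings; `top_k`,
`min_occurrence` (24) and `alpha` (0.05) are parameters. E/M annotation
uses the endpoint comparisons (0 vs 7 d; 7 d vs 3 d after removal):
directions may individually abstain, a single assigning direction decides,
and disagreement leaves the TF unassigned. The I/I2 classifier compares the
intermediate-timepoint extremum against both endpoints by rank-sum tests;
the endpoints-only comparison then separates E from M.

## Network construction

Mutual information is computed in nats on equal-frequency binnings with
B = ⌈N^⅓⌉ bins (ties broken by stable rank, so results are reproducible
bit-for-bit) and Miller–Madow corrected per entropy term,
MI_mm = MI_ML + (m_X + m_Y − m_XY − 1)/(2N), floored at zero. Interaction
signs come strictly from the Spearman correlation's sign; an exactly zero
correlation leaves the direction unsigned. An edge survives a cutoff pair
if it passes in at least one direction; conflicting forward/backward signs
remove the edge regardless of cutoffs. Pruning removes nodes with only
outgoing interactions in one pass — nodes orphaned by that pass are
retained, including as isolated nodes in the node list. The cutoff grid is
fixed (20 excitatory × 10 inhibitory values); an optional flag clips it to
the observed MI range.

## Ensemble simulation

Kinetics follow the random-circuit-perturbation convention: production
g ~ U[1, 100], degradation k ~ U[0.1, 1], Hill coefficient n ~ U{1..6},
fold change ~ U[1, 100] with the inhibitory Hill asymptote λ = 1/fold, and
interaction thresholds ~ U[0.02 M, 1.98 M] where M ≈ 91.8 is the median of
g/k over its ranges (solved from the closed-form CDF). This realizes the
half-functional rule: on a toggle-switch ensemble 35–65% of
model-interaction pairs have the regulator above its threshold. One initial
condition per model, log-uniform between each gene's minimal (inhibited)
and maximal (activated) level; multistability is explored across the
ensemble, not within a model. Integration is classic RK4, dt = 0.05, 50
time units, with negative excursions clipped at zero; processed states are
log2(x + 10⁻⁶), standardized per gene.

Perturbation phases multiply the signal genes' production rates by ×10000
(induction), ×1 (removal) or ×0.0001 (inhibition), always relative to the
original rates, and integrate by Euler–Maruyama with additive Gaussian
noise reflected at zero. The noise level is expressed in units of each
gene's unregulated scale g/k (amplitude = noise_level · g/k, from the
unperturbed rates): an absolute amplitude of 0.05 would be numerically
inert against expression scales of 10–1000. An optional deterministic
relaxation under the phase's parameters follows the stochastic window, so
transition counting compares attractor states rather than transient noise
excursions.

The signal+noise comparison (`evaluate.signal_noise_experiment`) uses a
deliberately sub-saturating signal (default factor 5) and noise 0.5·g/k
over 100 time units. This calibration mirrors the published procedure,
which states that signal strength and noise were selected so that E-state
models transition significantly more often with both signal and noise than
with either alone. At the full ×10000 induction every Hill term saturates
and per-model outcomes are deterministic — noise cannot add transitions in
that regime, in any direction; only a graded signal leaves a marginal
population for noise to convert.

## Evaluation

Role-annotated network TFs define complementary binary E/M references.
Binarization is per-gene 1-D two-means with deterministic extreme-value
initialization (the reference implementation's k-means has random
initialization; determinism is preferred for testing). The Hamming cutoff
is the largest d with exact random-match probability
2·Σ_{i≤d} C(k, i)/2^k < 0.05, counting a match to either reference;
networks with k ≤ 5 annotated TFs are unevaluable (even d = 0 gives
2/2^k ≥ 0.0625). Models within the cutoff of both references (possible
only when d ≥ k/2) count as unclassified. Experimental activities are
standardized with their own per-TF statistics before projection onto the
simulation's principal components; PC1 can be oriented from the E-model
centroid toward the M-model centroid. State clustering is Ward-linkage
hierarchical clustering on processed states with size-ordered labels.

## Problem sizes

The shipped study uses 12 TFs, 100 cells per timepoint (9600 cells),
500-model ensembles for network scoring and 2000-model ensembles where the
ensemble-size contract itself is exercised; these sizes make the full
analysis and test suite run in minutes on one CPU while leaving every
statistical check well-powered. All stages accept larger sizes unchanged.

## Known limitations

- The synthetic activity model is phenomenological (role-shaped means plus
  Gaussian noise); it does not simulate the circuit's own ODE dynamics, so
  activity data and simulation are linked only through the circuit's edge
  list and roles.
- Only ~7–10% of E-labeled ensemble models of a team circuit are bistable;
  transition statistics under saturating signals are therefore essentially
  deterministic per model.
- MI-based edge detection needs within-timepoint co-fluctuation; on data
  without it (or with correlated decoys) precision degrades.
- Some conditions of a switched-role study yield no evaluable network
  (fewer than 6 annotated E/M TFs among the network nodes) — the same
  context dependence reported for the real data.
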