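# Methods

## Model

The network is a discrete first-order-Markov dynamic Bayesian network.
Molecule nodes take trinary states x ∈ {−1, 0, +1}, meaning significantly
down-regulated, unchanged, or up-regulated *versus the matched control* at
the same time point. The joint density factorizes as

    p(x(0), …, x(T)) = ∏_i p(x_i(0)) · ∏_{t=1..T} ∏_i p(x_i(t) | pa(X_i(t)))

with all learnable parents in slice t−1, so any cyclic wiring (feedback
loops, self-loops) unrolls into an acyclic graph over time. Nodes are
independent at t = 0. Intra-slice edges are not modeled.

Two kinds of exogenous design nodes are fixed, never learned:

- `context` ∈ {cyt_protein, nuc_protein, transcript} is a parent of every
  molecule. Parameters are therefore *context-specific*: the same molecular
  edge may have different transition tables in the cytoplasm, the nucleus
  and on the transcriptome, which is how the three heterogeneous data types
  are integrated into one model.
- Binary intervention nodes `EGF_stim`, `SHH_stim`, `GLI_stim` parent the
  molecules their perturbation reaches (EGFR; PTCH1 and HHIP; GLI1). They
  are clamped constant within a series — a sustained stimulation — and make
  no assumption about perturbation efficacy: the stimulation merely shifts
  conditional probabilities, and unseen condition combinations can be
  queried at prediction time.

Parameters are estimated from transition counts with a Dirichlet
pseudo-count of 1 per cell: P(x | pa) = (N_{x,pa} + 1)/(N_{·,pa} + 3).
Unseen parent configurations fall back to uniform. Initial-slice marginals
are smoothed the same way, conditioned on the design nodes only.

A consequence worth knowing: because parameters are context-specific, a
(context × stimulation) configuration absent from the training series is
genuinely unpredictable (its rows are uniform). In the nine-series study
design this affects, e.g., GLI1 in the transcript context without GLI
induction whenever the only unstimulated transcript series is the one held
out.

## Structure learning

Each molecule's parent set is found by exhaustive search over subsets of its
allowed candidates (cap: 4 parents), scored with the mutual-information-test
score

    score(X; S) = 2·N·MI(X; S | F) − Σ_{j=1..|S|} χ²_{1−α_j}(l_j),
    l_j = (r_X − 1)(r_j − 1) · Π_{k<j} r_k · Π_{f∈F} r_f

where N is the number of observed transitions, F are the child's fixed
design parents (the mutual information is conditional on them — they encode
the experimental design, not hypotheses), candidates are ordered by
decreasing cardinality with name-lexicographic ties, and α = 0.10 is the
expected proportion of false-positive edges. The Π r_f factor is the
chain-rule degrees of freedom of the conditional independence test; with no
fixed parents the expression is the classical MIT penalty, and the penalty
is exactly the critical value of the χ² independence test at level α, which
keeps the per-family type-I rate calibrated. Because the score decomposes
over families and all learnable edges cross slices, per-node optimization is
exact (verified against joint brute force in the tests). The search prunes
subsets whose penalty already exceeds the attainable reward bound
2·N·H(X | F); ties go to the smaller set, then lexicographic order, so the
result is identical to unpruned enumeration.

Background knowledge enters in three regimes:

- **strong** — candidates restricted to literature parents (plus self-loops,
  which are always candidates by default);
- **weak** — all molecules are candidates, literature edges get a relaxed
  threshold α_j = 2α (the factor is configurable; α_j is clamped at 1);
- **none** — purely data-driven.

The default literature network (packaged as an editable SIF fixture) encodes
EGFR → {p38, AKT, ERK}, the cascades onto CREB, JUN and p70S6K, the
cross-talk edges ERK/AKT → GLI1 and ERK → GLI2, SHH → PTCH1,
PTCH1/HHIP → GLI1/GLI2, GLI2 → GLI1, SUFU–GLI links, and the transcriptional
feedback GLI1/GLI2 → PTCH1/HHIP. The 13-molecule default panel is likewise
editable; the measured panel of the emulated study is not enumerable from
its text, so this fixture is a reasonable reconstruction, not ground truth.

## Preprocessing

Per data type (protein RPPA and transcript arrays are analyzed separately):

1. transcript only: quantile normalization across samples and removal of
   probes whose median detection p-value is ≥ 1%;
2. technical-replicate correlation per molecule by pooled one-way nested
   ANOVA (blocks = biological replicates): the intraclass correlation
   (MSB − MSW)/(MSB + (k−1)·MSW);
3. precision weights 1/σ̂²(mean) from a lowess fit of residual s.d. against
   group mean (constant weights with a warning when fewer than 10 groups);
4. technical replicates are averaged within biological replicate, the
   averaged value weighted by k·w/(1 + (k−1)ρ̂) — the inverse variance of a
   mean of k equicorrelated observations;
5. per antibody/probe: weighted least squares on group (condition × time)
   and replicate factors; empirical-Bayes variance moderation with the
   inverse-chi-square prior moment-matched on log variances (the robust
   option winsorizes at 2.5 MADs); stimulated-vs-control contrasts per time
   point; two-sided moderated-t p-values;
6. Benjamini–Hochberg FDR within the data type; call = sign(logFC) when
   FDR < 5%, else 0; antibody-level calls are summarized per molecule as
   sign(mean), ties at exactly 0 mapping to 0 (conservative no-change).

The moderated-t machinery follows the published formulas directly; on a
shared fixture the log fold changes agree with limma to machine precision
and the p-values to rank correlation > 0.99 (exact agreement is not expected
because the variance prior and trend weights are estimated independently).
Only the trinary calls propagate downstream, which makes the pipeline robust
to those small p-value differences.

## Inference and validation

Posterior prediction uses likelihood weighting with per-step multinomial
resampling of whole particles: at t = 0, N = 1000 particles are drawn from
the initial distributions and weighted by the likelihood of the observed
nodes; at each subsequent step, particles are resampled proportional to
their weights, unobserved nodes are sampled from their CPTs, and the fresh
weights are the observation likelihoods of the new slice. The reported
posterior P(U(t) = v | o(0..t)) = Σ_s w_s(t)·1{u_s(t) = v} / Σ_s w_s(t) is
the filtered distribution; the most-probable state is the prediction, with
ties involving 0 (or three-way ties) resolved to 0 and −1/+1 ties resolved
by the larger training marginal. Because smoothing makes every observation
possible, a zero total weight is raised as an error rather than
renormalized. Resampling at every step is one operational reading of the
algorithm sketch the study describes; a fixed design choice here.

Leave-one-series-out validation holds out each of the nine series in turn,
learns structure and parameters on the remaining eight, hides the four
target molecules jointly in the held-out series, and scores the fraction of
matching time points. All 14 points count, including t = 0 (the initial
slice model predicts it). Accuracies are reported per target and pooled.

The parametric bootstrap fits (Γ̂, Θ̂) on all nine series, forward-samples
B = 100 datasets of identical shape (same contexts, conditions and lengths),
re-learns the structure on each with the same score configuration and prior
regime, and reports per-edge relative frequencies. Frequencies therefore
measure data support *within the chosen hypothesis space*. Edges with
support above 50% are reported as stable; self-loops are flagged for
display filtering. Note an asymmetry inherent to the method: an edge that
slips into the original fit is encoded in Θ̂ and hence amplified in the
resamples, so the bootstrap controls the support of typical null edges, not
of the already-selected ones.

## Synthetic-data generator

The generator emulates the study design: nine series = {cytoplasm, nucleus}
× {EGF, SHH, EGF+SHH} for protein and {EGF, GLI, EGF+GLI} for transcript,
T = 14 points, paired controls per context, 3 biological × 3 technical
replicates for protein and biological triplicates (with detection p-values)
for transcripts.

Ground-truth dynamics: a planted edge list with signs (+1 activation, −1
inhibition). A child's target state is the sign of the signed sum of its
parents' states, plus +1 per active stimulation parent; the target state
receives the mean strength of the contributing edges (default 0.9) and the
remaining mass splits evenly — the simplest monotone logic consistent with
pathway-diagram semantics. Parentless, unstimulated nodes are uniform, as is
the initial slice. CPTs are shared across contexts.

Expression emulation: value = molecule baseline (uniform 7–11 log units) +
state × effect size + biological noise + technical noise, where the noise
s.d. follows a log-linear mean–variance trend (variance decreasing in the
mean, σ₀ = 0.2 at the center) and the biological component is shared within
a biological replicate so technical replicates correlate at ρ = 0.5. The
control condition is emitted at baseline: trinary states are *defined* as
change versus control, so the control is the reference by construction.
Defaults (effect size 1.0 = 5σ₀) are typical of RPPA log-intensity data.

Two standard ground truths ship with the package: `study_ground_truth` — an
identifiable one-parent-per-child subset of the literature network, used
where per-edge recovery is measured (each planted edge has a non-redundant
signal, so bootstrap support near 1.0 is attainable); and
`literature_ground_truth` — the full literature network with multi-parent,
partially redundant wiring, used for the background-knowledge comparison,
where identification from ~100 transitions is genuinely hard. On the latter,
median leave-one-out accuracies land near the 70–75% regime for all three
prior modes, and the advantage of background knowledge is assessed by
pooling the strong- and weak-regime fold accuracies per replication and
sign-testing the median difference to the no-prior mode over 20
replications — the collective "with versus without background knowledge"
claim; the strong regime alone is statistically indistinguishable from the
no-prior mode at this signal strength.

What the generator does *not* emulate: probe-level microarray artifacts,
background correction, batch effects, unpaired replicate structure,
continuous (ODE-like) dynamics, or measurement of only a probe subset.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated generative assumptions, not performance on any particular
real dataset.

## Numerical choices and problem sizes

- All randomness flows through explicit integer seeds or spawned
  `numpy` generators; identical seeds give bit-identical outputs, and the
  CLI derives one independent substream per stage from the global seed.
- CPT rows validate to sum 1 within 1e−12 and stay strictly positive;
  posterior rows within 1e−9.
- Chi-square quantiles are cached; 0·log 0 := 0 throughout; empty parent
  sets score exactly 0.
- Exact-inference cross-checks enumerate 3-node models (27 joint states);
  search-oracle checks run 1000 random datasets with ≤ 5 candidates and
  ≤ 200 transitions; parameter recovery uses ~3.5 × 10⁴ sampled transitions
  (≥ 10⁴ per parent configuration); the bootstrap experiments use B = 100
  over 10 seeds and the prediction experiments 20 replications at N = 1000
  particles — sizes chosen to keep the whole validation reproducible on a
  single CPU in minutes.

## Known limitations

- The MIT score's chi-square penalty assumes the plug-in MI's null
  distribution; at very small N (a handful of transitions) the calibration
  is approximate.
- Strong-mode results are conditional on the literature fixture being
  approximately right; it is shipped as editable data for exactly that
  reason.
- The bootstrap amplification asymmetry described above means edge
  frequencies should be read as stability of the fitted model, not as
  false-discovery control.
- Filtering (forward-only) posteriors are reported; no backward smoothing
  pass is implemented.
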