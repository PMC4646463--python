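# dbnpipe

Dynamic Bayesian network (DBN) modeling of cross-talk between EGFR and sonic
hedgehog (SHH) signaling from discretized time-series expression data.

## The problem

Sustained stimulation experiments (EGF, SHH, or combined; GLI1 induction in
place of SHH for transcriptomics) measure 13 pathway molecules in three
biological contexts — cytoplasmic protein, nuclear protein (reverse-phase
protein arrays) and transcript abundance — over 14 time points with replicate
structure. The analysis question is dynamical: which molecule at time *t−1*
statistically drives which molecule at time *t*, how confident can one be in
each such edge given data of this size, and can the fitted network predict
the activity of held-out key molecules (the transcription factors GLI1, CREB
and JUN, and the kinase p70S6K)?

`dbnpipe` implements the full chain for this class of experiments, and a
synthetic-data generator that emulates the study design so every stage is
testable without external downloads:

1. **preprocess** — replicate-level log-intensities are tested per time point
   against control with a weighted moderated-*t* linear model (factors
   *group* = condition × time and *replicate*; lowess mean–variance precision
   weights; empirical-Bayes variance shrinkage; technical-replicate
   correlation), discretized at Benjamini–Hochberg FDR 5% into trinary states
   (−1 down, 0 unchanged, +1 up), and summarized per molecule as the sign of
   the mean antibody-level call.
2. **dbn_core** — a first-order-Markov DBN over the 13 molecule nodes plus a
   3-level `context` node (parent of every molecule) and binary intervention
   nodes `EGF_stim`, `SHH_stim`, `GLI_stim` wired to their receptor-level
   targets (EGFR; PTCH1/HHIP; GLI1). Parameters Θ are conditional probability
   tables estimated with a Dirichlet pseudo-count of 1.
3. **structure_learning** — exact per-node parent-set search with the
   mutual-information-test (MIT) score, `2·N·MI(child; parents)` minus
   chi-square critical values at type-I error rate α = 10%, under three
   background-knowledge regimes: *strong* (literature parents only), *weak*
   (all parents, literature edges at a relaxed threshold) and *none*.
4. **inference** — sequential importance sampling (likelihood weighting,
   N = 1000 particles, per-step resampling) for the posterior state of
   unobserved molecules given a partially observed series.
5. **evaluation** — leave-one-of-nine-series-out prediction accuracy and a
   parametric bootstrap (B = 100 refits on model-sampled datasets) scoring
   edge stability; edges above 50% support are reported.

## Worked example

```python
import dbnpipe as d

# ground truth -> study-shaped data -> expression -> discretize -> learn -> validate
truth = d.make_ground_truth_model(d.study_ground_truth(edge_strength=0.9))
series = d.sample_study_series(truth, seed=1, include_controls=True)
table = d.emulate_expression(series, d.NoiseModel(effect_size=1.2), seed=2)
calls, summary, trinary = d.discretize_table(table)

cfg, prior = d.ScoreConfig(alpha=0.10), d.PriorKnowledge(mode="strong")
structure = d.learn_structure(trinary, cfg, prior)
result = d.loo_validate(trinary, cfg, prior, N=1000, seed=3)
freqs = d.parametric_bootstrap(trinary, cfg, prior, B=100, seed=4)
stable = d.stable_edges(freqs, cutoff=0.5)
```

Output (printing the intermediate quantities):

```
9 series x 14 time points, 72.8% of contrasts significant at FDR 5%
learned 11 molecule edges, e.g. ('GLI2',) -> GLI1
target   median      q25      q75
  CREB 0.642857 0.642857 0.928571
  GLI1 0.785714 0.714286 0.857143
   JUN 0.714286 0.714286 0.785714
p70S6K 0.785714 0.714286 1.000000
   all 0.785714 0.714286 0.839286
11 stable edges (>50% bootstrap support); top:
parent child  frequency  self_loop
   AKT  CREB        1.0      False
  EGFR   AKT        1.0      False
  EGFR   ERK        1.0      False
```

Reading this: discretization turns the replicate-level table into nine
trinary series; strong-mode search recovers the planted wiring (here the
GLI2 → GLI1 edge of the SHH cascade); held-out molecules are predicted with
median accuracies around 0.64–0.79 across the nine folds (clearly above the
1/3 chance level); and every planted edge survives all 100 bootstrap refits.

The same pipeline runs from the shell:

```sh
dbnpipe --seed 7 --out-dir out run --stages simulate,discretize,learn,validate,bootstrap
dbnpipe --config run.yaml learn --mode weak --alpha 0.1 --max-parents 4
```

To analyze real data, write the expression table as TSV with columns
`molecule, antibody, context, condition, time, bio_rep, tech_rep, value,
detection_p` (contexts `cyt_protein`/`nuc_protein`/`transcript`; conditions
`control`, `EGF`, `SHH`, `EGF+SHH`, `GLI`, `EGF+GLI`) and start from the
`discretize` stage. The literature prior network is a packaged, editable SIF
fixture (`--prior my_edges.sif` to replace it).

## Documentation

See `docs/methods.md` for the model, the synthetic-data generator, numerical
choices and known limitations.
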