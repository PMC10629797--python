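# zsustain

Subtype and Stage Inference (SuStaIn-style) for regional brain-atrophy
z-scores, built as a fully tested pipeline that runs end-to-end on
synthetic cohorts with known ground truth:

1. **io** — ROI dictionary (28 cortical-thickness + 12 subcortical-volume
   regions), CSV/TSV cohort tables, TOML run configuration, deterministic
   TSV exports (positional-variance diagrams, subject posteriors,
   per-stage severity bands).
2. **adjust** — control-referenced covariate adjustment: per
   (region, scanner stratum) conjugate Gaussian linear model (intercept,
   TIV, sex, centred age, centred age²) fitted on controls; subject
   measures become residual z-scores, sign-flipped so larger = more
   atrophy; optional ipsilateral/contralateral regrouping by seizure-focus
   laterality.
3. **event_model** — the piecewise-linear z-score progression model:
   events are (region, threshold) pairs, a subject at stage *k* is
   Gaussian noise around interpolated trajectories; per-stage likelihoods
   and the mixture log-likelihood over several progression patterns.
4. **fit** — greedy multi-start sequence optimisation, hierarchical
   cluster splitting with EM over (fractions, sequences), Metropolis MCMC
   over event orderings with Dirichlet fraction steps,
   positional-variance diagrams, per-subject subtype probabilities,
   weighted stage, >50% assignment cut-off and stage-zero flagging.
5. **selection** — k-fold cross-validation; CIC = held-out deviance;
   parsimony rule (smaller C preferred within ΔCIC < 6); per-subtype
   cross-fold similarity via optimal matching of PVD overlap.
6. **synthetic** — cohort generator drawing from the progression model
   itself and inverting a known control model back to raw units, plus
   clinical covariates (duration, convulsions, seizure frequency, ASM
   count) statistically linked to true stage/subtype.
7. **assoc** — correlation-matrix PCA with Kaiser (λ > 1) retention,
   seeded percentile-bootstrap Spearman correlations, chi-squared and
   Kruskal-Wallis tests, per-subtype clinical characterization.

## CLI

```bash
zsustain simulate  --seed 1 --out sim/ --n-patients 400 --n-regions 10 --subtypes 2
zsustain adjust    --seed 1 --roi sim/roi_measures.tsv --clinical sim/clinical.tsv --out adj/
zsustain fit       --seed 1 --z adj/zscores.tsv --subtypes 2 --iters 50000 --out fit/
zsustain crossval  --seed 1 --z adj/zscores.tsv --max-subtypes 4 --folds 10 --out cv/
zsustain associate --seed 1 --posteriors fit/subject_posteriors.tsv \
                   --clinical sim/clinical.tsv --cohort focal --out assoc/
```

All stages accept `--config run.toml` (keys mirror
`zsustain.config.RunConfig`; production defaults are 25 start points,
1 000 000 MCMC iterations, up to 4 subtypes, 10 CV folds, 5000 bootstrap
replicates). Identical (config, seed) pairs reproduce outputs
byte-for-byte.

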