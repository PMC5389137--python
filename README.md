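# caniform

Landmark-based geometric morphometrics for telling dog skulls from wolf
skulls — and for deciding, with honest uncertainty, which group an
unidentified (e.g. fossil) skull belongs to.

The question of when wolves became dogs hinges on a handful of ancient
canid skulls. Simple caliper indices (snout length over skull length and
the like) mix size into shape and famously fail to separate the groups.
This package implements the landmark-based alternative end to end:

- **Procrustes superimposition with object symmetry** — dorsal and
  ventral landmark views are merged by a rigid least-squares fit, every
  configuration is rescaled to unit centroid size
  (CS = √Σ‖xᵢ − x̄‖²), and each configuration is superimposed jointly
  with its mirrored, relabelled copy; analyses use the symmetric
  component. Digitization error is checked with a Procrustes ANOVA
  (Goodall's F).
- **Procrustes form-space PCA** — covariance PCA of
  [shape coordinates | ln CS], so size, allometry and shape are analysed
  together; unknowns are projected onto the frozen reference axes. The
  number of interpretable PCs is chosen by the classical test of
  equality of trailing eigenvalues.
- **Balanced-resampling QDA with typicality** — the wolf sample is
  repeatedly subsampled to the dog sample size; each iteration rebuilds
  the form space, refits a quadratic discriminant with equal priors
  (P_prior = 0.5), and accepts a call only when the posterior
  P_post > 0.90. Typicality probabilities (chi-square tail of the
  pooled-covariance Mahalanobis distance) flag specimens that fit
  *neither* group. Reference discrimination is summarized by
  leave-one-out accuracy, Klecka's tau and Wilks' lambda.
- **Cranial-index negative control** — the four classical log₁₀
  distance-ratio indices, their PCA, and bivariate convex-hull exports,
  which demonstrate the dog–wolf overlap the landmark method resolves.
- **A synthetic skull generator** — no landmark data are deposited for
  the original sample, so a fully parameterized generator produces
  36-landmark bilateral datasets (91 dogs vs 258 + 57 wolves, two views,
  two replicates) with a "stop"-like mean-shape contrast, a shared
  allometric trend, structured within-group variation and recorded
  ground truth for recovery tests.

The statistical estimators follow scikit-learn conventions
(`GeneralizedProcrustes`, `FormSpacePCA`, `ThresholdQDA`, `ResampledQDA`
with `fit`/`transform`/`predict` and trailing-underscore fitted
attributes); module-level functions wrap them for script use.

## Worked example

```python
import caniform as cf

params = cf.SyntheticParams(unknowns={"dog": 1, "arctic_wolf": 1, "midpoint": 1})
dataset, truth = cf.simulate_dataset(params, seed=7)
result = cf.run_pipeline(dataset, cf.RunConfig(n_iter=200, seed=7))

print(result.summary)
print(result.report.to_frame().to_string(index=False))
```

prints

```
95.7% correctly classified (Tau = 0.914, Wilks' lambda = 0.155, Mbox = 36.71, df = 28, p = 0.125)

          specimen  avg_Ppost_dog  avg_Ppost_wolf  pct_dog  pct_wolf  pct_undetermined qda_result  pct_TypP_le_0.05 typicality_group
        unk_dog_01         1.0000          0.0000    100.0       0.0               0.0        Dog               0.0              Dog
unk_arctic_wolf_02         0.0001          0.9999      0.0     100.0               0.0       Wolf               0.0             Wolf
   unk_midpoint_03         0.7847          0.2153      6.0       0.0              94.0        Ind               0.0              Dog
```

Reading the table: the simulated dog and wolf unknowns are called Dog and
Wolf in 100% of the 200 resampling iterations with posterior > 0.90,
while the deliberately intermediate specimen is undetermined in 94% of
iterations and receives the final call "Ind" — the engine refuses to
force an ambiguous skull into either group. On the same run the
reference sample cross-validates at 95.7% correct (tau = 0.914, Wilks'
lambda = 0.155), the sphericity test retains 7 PCs per iteration, PC1 is
a size–allometry axis with |r(PC1, lnCS)| = 0.99, and wolves are
significantly larger than dogs (permutation p ≈ 0.001).

## Command line

```sh
caniform simulate --seed 1 --out skulls.tsv
caniform validate skulls.tsv
caniform all skulls.tsv --seed 1 --n-iter 1000 --out-dir results/
```

Subcommands `superimpose`, `formspace`, `classify` and `indices` run
individual stages; every output file is stamped with the seed and a
config digest.

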