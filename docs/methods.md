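# Methods

## Scope and model

The package implements a small-cohort radiomics classification protocol:
per-task three-step feature selection followed by forward logistic model
building under imbalance-adjusted bootstrap resampling (IABR) with 0.632+
performance estimation, order selection, and DeLong comparisons. The
statistical model is ordinary binary logistic regression on standardized
features,

    g(x_i) = beta0 + sum_{j=1..v} beta_j x_ij,
    P(y_i = 1 | x_i) = exp(g) / (1 + exp(g)),

with v (the "model order") grown from 1 to 5. The protocol assumes
exchangeable rows within a class, features on arbitrary monotone scales
(all screening statistics are rank-based), and a cohort small enough that
refitting a logistic model a few hundred thousand times is cheap.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `rho_max` | 0.8 | Spearman threshold of the redundancy filter (dimensionless) |
| `alpha` | 0.05 | two-sided significance level of the Wilcoxon screen |
| `k` | 5 | number of top mutual-information candidates kept |
| `b` | 1000 | bootstrap replicates per IABR evaluation |
| `max_order` | 5 | largest model order grown by forward selection |
| `epsilon` | 0.01 | AUC tolerance of the "simplest near-best order" rule |
| `imbalance_adjusted` | true | class-balanced in-bag draws vs plain bootstrap |
| `ridge` | 1e-6 | L2 penalty on slopes (never the intercept) in the logistic fit |

`alpha = 0.05` and the classification threshold p >= 0.5 are conventions;
the source protocol states neither. The 0.632+ correction is applied with
chance level 0.5 to all four reported metrics (AUC, sensitivity,
specificity, accuracy) uniformly, since corrected values of all four are
reported downstream; strictly the chance level of sensitivity alone is
not 0.5, but a uniform treatment keeps the four numbers comparable and
the AUC — the quantity that drives every decision — is unaffected.

## Algorithmic choices

**Redundancy filter.** The full |Spearman| matrix is computed once; while
any pair exceeds `rho_max`, the offending pair with the largest |rho| is
located and its member with the larger mean |rho| against all currently
surviving features is dropped (ties: the later catalogue position).
A one-line description of this filter admits several removal orders; this
one is pinned because it is deterministic, needs no recomputation of the
matrix, and matches the behavior of the widely used highest-pair-first
filters. Correlations against constant columns are defined as 0 with a
warning.

**Wilcoxon screening.** Rank-sum p-values are exact (full null
distribution) when the smaller group has <= 10 observations and there are
no ties, asymptotic with tie and continuity corrections otherwise; the
paired signed-rank variant discards zero differences, is exact for <= 12
nonzero pairs without tied magnitudes, and degenerates to p = 1 with a
warning when all differences vanish. For the lesion-vs-healthy task both
the unpaired and the paired screens are computed and reported; downstream
steps use the unpaired survivors (on the reference analysis both settings
produced the same top-ranked set, and the unpaired screen generalizes to
the grading tasks).

**Mutual information.** Features are discretized by average-rank
equal-frequency binning into ceil(sqrt(n)) bins (capped at 10, or as
configured); tied values always share a bin, so a constant feature scores
exactly 0, and for distinct values the codes depend on ranks only, making
the estimate invariant under strictly monotone transforms. MI is the
plug-in estimate on the bins-by-class contingency table, in nats. Ranking
ties are broken by catalogue order, making step III deterministic.

**Balanced bootstrap.** Each in-bag draw picks a class with probability
1/2, then an instance uniformly within the class, so in-bag positive
counts are Binomial(n, 1/2) by construction. Draws are unconditional:
when the minority class is very small (7 of 38), all of its instances are
in-bag in a substantial fraction of replicates and the out-of-bag set
then lacks that class. Such replicates are skipped at evaluation time
(the out-of-bag mean averages the scoreable replicates) rather than
redrawn: redrawing would condition accepted samples on incomplete
minority coverage and visibly bias the in-bag class balance the
adjustment exists to guarantee (measured mean in-bag positives 17.6
instead of 19 under redrawing at 7/31).

**Logistic fit.** Features are standardized to zero mean and unit sample
SD (parameters stored in the model so it can be re-applied to raw
values); the likelihood is maximized by Newton iterations with step
halving, with a fixed ridge of 1e-6 on the slopes so separable data —
common at n = 38 with strong features — yield finite, deterministic
coefficients. Constant in-bag feature columns raise an error (and the
affected bootstrap replicate is skipped).

**Forward selection.** One common IABR index set (derived from the seed)
scores all candidate additions while a model is being grown, and a fresh
IABR draw re-evaluates the per-order winners, mirroring the
build-then-re-evaluate protocol; candidate ties keep the higher MI rank.
Per-task seeds in a study are `base_seed + task_index`, so adding a task
never perturbs the others, and a fixed seed makes the whole study
bit-reproducible.

**DeLong comparisons.** Implemented with placement values: variance of
the AUC difference from the empirical covariance of per-positive and
per-negative placements, two-sided normal p-value, Bonferroni-multiplied
by the number of model pairs (10 for five orders). Identical score
vectors short-circuit to p = 1; zero variance with unequal AUCs raises an
error. The compared scores are the apparent (full-data) scores of the
per-order final models.

## The synthetic cohort generator

The generator emulates the *structure* of a per-subject radiomic feature
table from the reference cohort: 38 patients with grades G1/G2/G3 =
7/15/16, one HCC VOI per patient plus one paired healthy-tissue VOI with
grade NA; 386 catalogue features of which 40 blocks of 8 are
latent-factor redundant (x = lambda*z_block + sqrt(1 - lambda^2)*eps,
lambda = 0.95, giving within-block Spearman ~0.89 so step I collapses
each block and ~106 features survive, the same order as a real
redundancy-heavy catalogue); noise is Student t with 20 degrees of
freedom scaled to unit variance, so rank statistics are exercised
off-Gaussian. Two designated features per task carry additive mean
shifts of 2 SD: a tissue shift for HCC-vs-HT, and grade-ordered shifts
(G1 <= G2 <= G3) for the grading contrasts, mimicking monotone
aggressiveness. `tasks_with_effects` restricts the planted effects to a
subset of tasks, which recovery analyses use to isolate one contrast
(grade-ordered shifts otherwise also separate HCC from HT rows).

What the generator does *not* emulate: real marginal feature
distributions (no distributional information about the source cohort is
available; defaults are stated assumptions), scanner/vendor batch
effects, inter-feature correlation beyond the block structure, and any
voxel-level imaging physics. Passing recovery tests therefore show that
the pipeline recovers effects of the planted kind at the planted size
under the cohort's geometry — not that real radiomic effects of clinical
interest are of that kind or size.

## Post-selection optimism (known limitation)

Steps I-III are computed on all rows of a task, and the bootstrap then
resamples those same rows. A feature that survives the alpha = 0.05
rank-sum screen at 38-vs-38 necessarily has |AUC - 0.5| >= ~0.13 *on the
very data the out-of-bag sets are drawn from*, so on an all-noise cohort
the chosen model's 0.632+ AUC lands around 0.65-0.8, not at chance. The
0.632+ correction repairs overfitting of the *coefficients*, not of the
*feature selection*, which happened outside the bootstrap. The package
reports this honestly (see `analysis/04_recovery_experiment.py`); an
unbiased estimate would require nesting all selection steps inside each
bootstrap replicate, which is outside this protocol. Consequently,
absolute 0.632+ values from this pipeline should be read as
selection-conditional, and null-band behavior at chance level holds only
for pre-specified features (tested as such).

## Problem sizes used by the test suite and acceptance script

Module tests run on cohorts of 6-38 patients with B = 30-200; the
acceptance tests use 20-seed experiments at B = 200 (recovery and null),
1000-sample bootstrap distribution checks, 500-replicate DeLong
calibration, and a B = 50 double run for bit-level reproducibility. The
acceptance script runs the full five-task study at the protocol's
B = 1000 on one fresh cohort and a 10-cohort recovery experiment at
B = 200. These sizes keep a full run in the low minutes on one core
while leaving every estimate's Monte-Carlo error well inside the margins
asserted.
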