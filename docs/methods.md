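# Methods

## Choice models and conventions

Both responder models map a mini-UG game to an accept utility; rejection
always has utility 0. For inequity aversion this is exact (rejection zeroes
both payoffs, so every Fehr–Schmidt term vanishes). For the reciprocity
model it is a convention we document rather than derive: recomputing
kindness terms at the rejection payoffs would make the accept−reject
utility difference identical across conditions and destroy the model's
defining prediction (highest acceptance when the proposer had no
alternative); setting `U(reject) = 0` — both payoffs zero, no reciprocity
term accrues — reproduces the intended predictions and is what the
package implements.

The responder-kindness reference point is asymmetric as published:
`(max(x_i, x_i') + min(x_j, x_j')) / 2` mixes the proposer's best
alternative with the responder's worst. We implement it verbatim; a
`symmetric_kindness` flag switches to `(max(x_i, x_i') + min(x_i, x_i'))/2`
for sensitivity analysis (default off). The context switch `c` is 0 in the
no-alternative condition and otherwise the sign of the accept-action `k_j`
(the only action with a nonzero reciprocity term).

Choice probabilities use a two-action softmax with temperature fixed to 1;
a free-temperature variant instead estimates a per-subject inverse
temperature in `[1e-3, 50]` and adds one parameter to each model's BIC
count. Utilities are max-shifted before exponentiation, so probabilities
never overflow and are invariant to constant shifts.

## Fitting

Per subject, the log likelihood `ll = Σ_t log p(choice_t)` is maximized
over the unit parameter box by L-BFGS-B from 20 Latin-hypercube starts
(seeded; `ftol = 1e-8`). Likelihood terms are aggregated over unique
(game, outcome) pairs, which makes a 168-trial fit a handful of floating
operations per evaluation. Probabilities are floored at `1e-12` before the
log so boundary parameters keep the objective finite. With a free
temperature, the fixed-temperature optimum (at inverse temperature 1) is
added as an extra start, so freeing the temperature can never lower the
maximized likelihood. An exhaustive 0.01-step grid evaluation
(`grid_max_log_likelihood`) is provided as an optimizer-quality check; the
test suite holds the optimizer to "never below grid max − 1e-6" over 100
synthetic subjects. BIC uses the natural log.

## Mediation

Three OLS equations share the covariates (sex, IQ): mediator on age;
outcome on age + mediator; outcome on age. This yields paths `a`, `b`,
direct `c'` and total `c`, with the exact identity `c = c' + a·b`.
Inference on the indirect (and direct) effect uses a bias-corrected (BC,
not BCa) percentile bootstrap over subjects: the percentile cut points are
shifted by `2·z₀` where `z₀ = Φ⁻¹(fraction of bootstrap replicates below
the point estimate)`, clipped away from 0/1 by `1/(B+1)`. Default
`n_boot = 10 000` (1 000 minimum); variables are analyzed in natural units
(no standardization), so paths are in mm/yr, index-units/mm, etc. The
ratio indirect/total is reported as NaN when the total effect is
numerically zero. Bootstrap path fits use plain least squares for speed;
the headline age regression goes through statsmodels for its t and p.

Degenerate inputs: a zero-variance mediator raises; bootstrap resamples
that happen to have a constant mediator are dropped from the BC
distribution. When both generator noises are set to zero the mediator is
an exact linear function of age and the outcome equation is
rank-deficient — path `b` is then not identifiable, which is a property of
the model, not of the implementation.

## Decoding

Spatial similarity is the Spearman correlation over the voxels valid
(finite and nonzero) in both maps; at least 10 shared voxels are required.
First-stage p-values permute the statistic map's voxel values within the
joint mask (two-sided on |rho|, add-one rule). This null assumes
exchangeable voxels: it does **not** preserve spatial autocorrelation, so
on smoothed maps the p-values are optimistic. The package keeps the simple
scheme deliberately — it matches the described procedure — and the
calibration tests therefore use unsmoothed independent noise maps, where
the null is exact.

Rank stability: topics are sorted most-extreme-first (a `direction` flag;
default 'negative', the convention when the statistic map correlates
negatively with the variable of interest). For the topic at rank r, the
correlation vector is permuted and the topic's own correlation is compared
with the mean of the permuted values at ranks below r; the p-value counts
the permutations where it fails to exceed that mean (ties one half,
add-one rule). A dominant rank-1 topic thus attains `1/(n_perm+1)` and a
fully tied vector gives ≈0.5 everywhere. The bottom rank has no lower
ranks and is reported as p = 1. Ties in rho are broken by topic name, with
a warning. FDR uses Benjamini–Hochberg at q = 0.05 on the first-stage
p-values.

## Synthetic-data generator

The generator emulates the study conditions the analyses assume: 84
subjects, ages uniform on 9–23, IQ ~ N(105, 12²), sex a pure covariate
(independent of everything by default); 168 single-shot games per subject,
56 per condition in seeded pseudorandom order, with unfair chosen offers
two thirds of the time (within the two alternative conditions the chosen
division is unfair with probability ½, so the overall fraction works out);
offers 8/2 and 7/3 against alternatives 5/5, the mirror split, or no
alternative.

Preferences shift with age: latent `θ(age) = θ_max·logistic((age −
17.5)/2)` plus N(0, 0.08) noise, clipped to [0, 1] (crossover in late
adolescence); `α ~ N(0.7, 0.15²)` and `β ~ N(0.15, 0.08²)` are age-flat;
each subject's generating model is reciprocity with probability
`logistic((age − 17.5)/2)`. ROI thickness is `3.6 − 0.05·age + N(0, 0.15²)`
mm — a 0.05 mm/yr adolescent thinning rate — and the constructed
reciprocity index is `300 − 100·thickness + 0·age + N(0, 20²)`, so the true
indirect effect is `(−0.05)·(−100) = +5` index units per year with a zero
direct effect (pure mediation). These effect sizes make recovery at n = 84
reliable but not trivial: the indirect-effect t is ≈7 and the age slope of
the fitted index ≈20/yr.

Volumetric fixtures are 20³ grids of unit-variance Gaussian noise smoothed
with a 1-voxel kernel. An 8³ contiguous region carries −4.0 signal in the
statistic map and +4.0 in one designated topic ("social_inference") among
41 topics, giving the target a spatial rho of ≈−0.15 against a smooth-noise
chance floor of |rho| ≈ 0.05–0.1; the region size and amplitude were set
from that signal-to-noise calculation. Because smoothing violates the
voxel-exchangeability null, many noise topics also reach nominal
significance on these fixtures — the designed claim is the target's rank,
not the false-positive rate, which is only calibrated on unsmoothed maps.

What the generator does **not** emulate: the original task's exact trial
composition table, proposer-side behavior, learning or satiation across
trials, surface-based cortical geometry, realistic map autocorrelation
structure, or any of the undeposited human data values. Passing tests
therefore demonstrate that the pipeline recovers structure it was designed
to recover at realistic sizes — not that the original study's numbers are
reproduced.

## Pipeline and reproducibility

`run_pipeline` chains generate → simulate choices → fit both models →
reciprocity index → acceptance summary → age regression → thickness
mediation → map decoding. Every stage draws from a seed-sequence child of
the master seed with a fixed per-stage key, so results are bit-identical
for a fixed config and independent of stage execution order. Mediation is
reported on two routes: the behaviorally fitted index (the analysis route
a real study would run) and the generator-constructed index (the
known-truth recovery route). In the default synthetic world the fitted
index is driven by age but conditionally independent of thickness given
age, so only the constructed route carries a true indirect effect; tests
and the acceptance script use the constructed route for recovery claims.
Default pipeline sizes (n_boot = 2000, n_perm = 1000, 20 optimizer starts)
keep a full run near ten seconds; the heavier unit defaults (10 000
bootstrap draws and permutations) remain available through the function
arguments.
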