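# Methods

## The model

Every inferential step in this package rests on one model: a Gaussian
linear mixed model with crossed random intercepts for subject and item,

    y = X beta + Z_s u_s + Z_i u_i + eps,
    u_s ~ N(0, sigma_s^2 I),  u_i ~ N(0, sigma_i^2 I),  eps ~ N(0, sigma^2 I).

The response is either a lexical-decision reaction time (ms) or a signed
source-estimate amplitude at one time point (dSPM-like units). Random
*slopes* are deliberately out of scope: the designs targeted here test a
single within-subject, within-item two-level factor (PrimeType) on
modest per-cell counts, where intercept-only crossed structures are the
conventional specification.

Fitting (`megprime.mixedmodel.CrossedLMM`) profiles the likelihood over
the variance ratios lambda_s = sigma_s^2/sigma^2 and
lambda_i = sigma_i^2/sigma^2. For fixed ratios, the GLS fixed effects,
the profiled residual variance and the (restricted) likelihood are closed
forms; the remaining 2-D optimization uses Nelder–Mead on a square-root
parameterization (ratios can hit exactly 0; variance components are
never negative). All n-dimensional products reduce via the Woodbury
identity to q = n_subjects + n_items dimensions, so a fit costs a handful
of q x q Cholesky factorizations regardless of trial count. Agreement
with statsmodels MixedLM and lme4 is pinned by tests (coefficients to
1e-5, ML log-likelihoods to ~1e-5).

Conventions: REML whenever a single fit's t-values are reported; ML for
every likelihood-ratio test of nested fixed-effect structures
(chi^2 = 2 Delta logLik, clipped at 0; the full model is additionally
warm-started from the reduced optimum so the nesting inequality holds
numerically). t-values are coefficient/SE with no degrees-of-freedom
correction, to match the fixed |t| > 1.96 cluster-forming threshold. A
constant response returns an exact-fit result with zero variance
components and zero t-values. If an added "interaction" column lies in
the span of the reduced design (e.g. identically zero), the LRT returns
chi^2 = 0, p = 1 rather than a rank error.

## Millisecond-wise testing and cluster-mass correction

A separate model is fitted at each time point of the analysis window;
the fixed-effect t (or, for interactions, sqrt(chi^2) from the nested
LRT) forms a statistic series. Clusters are maximal runs of consecutive
points strictly exceeding the threshold (1.96; sqrt(chi^2) > 1.96 is
chi^2_1 > 3.84, i.e. p < .05 uncorrected) with one sign; a cluster's
mass is the sum of its member statistics (Sigma-t). Window-edge clusters
are legal; values exactly at the threshold are not members.

Family-wise correction compares each observed |mass| with the
permutation distribution of the *maximum* |mass|: the independent
variable is relabeled, the entire series and its clusters are recomputed,
and the largest |mass| per relabeling forms the null. Per-cluster
Monte-Carlo p-values use the add-one estimator
(1 + #{null >= |mass|}) / (1 + n_perm), hence lie in (0, 1]; an
observation with no cluster reports p = 1. Each analysis corrects only
within its own window; no correction is applied across analyses.

**Permutation scheme.** PrimeType labels are exchanged *within subject*,
preserving every subject's related/unrelated counts (and, in balanced
designs, the subject margins exactly); under this scheme the subject
intercepts are ancillary and the null is exchangeable even with
arbitrary between-subject differences. A free (across-subject) scheme is
available (`scheme="free"`). For interaction tests, only factor A is
permuted within subject while the covariate B stays attached to its
trials, breaking exactly the A x B pairing under test.

**Score-type approximation.** Refitting variance components for every
permutation x time point is wasteful (they are ancillary to the
relabeling to first order). Permuted statistics therefore hold the
variance ratios at the observed per-timepoint estimates and recompute
the GLS coefficient, its SE (residual variance re-profiled per
permutation) and the resulting t — batched over all permutations with
one Cholesky factor per time point. An exact-refit mode exists
(`mode="refit"`) and the two agree within Monte-Carlo error on small
fixtures; exact refits cost ~100 ms per permutation and are reserved for
validation. The observed series always comes from full (RE)ML fits.

## Windows and peaks

Early-response analysis windows are 50 ms wide: fixed at 75–125 ms for
the visual M100, centered at a *detected* peak for the M170 (grand-mean
ROI activity, searched in 100–250 ms, absolute extremum, ties to the
earliest sample, edge peaks logged), and the late lexical window is the
fixed interval 300–500 ms. Window bounds are inclusive on the sample
grid; a peak at latency p yields (p - 25, p + 25).

## Functional ROI

The fROI is drawn on a labeled source grid from a localizer contrast
independent of the tested conditions: the priming difference
(unrelated - related), *sign-aligned* to each source's local evoked
response (facilitation = reduction of |activity| for related primes),
pooled over the identity and regular conditions and averaged over the
localizer window. The peak source is the mask-internal source
(fusiform + inferior temporal by default) with the largest facilitatory
difference; the fROI extends to mask-internal sources at >= 50% of the
peak's value, restricted to the grid-connected component containing the
peak (the extent criterion of a hand-drawn ROI is not a published rule;
the 50%-of-peak connected-component rule is this package's stand-in, and
the fraction is configurable). Priming in the fROI is then tested on
irregular and pseudo-irregular trials only; a simulation test confirms
the localize/test split preserves nominal type-I error on null test
conditions. The localizer window itself is centered at the peak of the
mask-averaged, sign-aligned facilitation time course.

## Behavioral screening and tests

Subjects are excluded when their mean RT, or their RT standard
deviation, exceeds the across-subject mean of those summaries by more
than 2 SD (computed over subject-level summaries on correct word
trials, inclusively — no leave-one-out). Trials are trimmed when RT <
300 ms or RT > condition mean + 2 SD pooled across subjects, computed
once on the pre-trim table (single pass, not iterated); removed trials
go to a rejection log. Per condition, the priming effect is the LMM
coefficient for PrimeType (unrelated - related adjusted for crossed
intercepts) — the raw marginal difference is reported alongside but
becomes item-confounded once exclusions unbalance the two
counterbalancing versions. Significance uses the within-subject
permutation p with the add-one estimator (the package's reproducible
re-specification of "Monte-Carlo" mixed-model p-values, whose original
mechanism is not reproducible from its description). The
PrimeType x Pseudo-irregularity contrast on the irregular +
pseudo-irregular subset is a nested-model ML LRT with an analytic
chi^2_1 p.

Note that the 2-SD ceiling trim is asymmetric by construction: it
removes more slow unrelated than related trials and therefore attenuates
every priming estimate (by ~15% at the default noise level, measured by
simulation). This mirrors what the same rule does to real data; no
correction is applied.

## The synthetic study generator

`megprime.synth` emulates the trial structure and signal assumptions of
a 16-subject masked-priming lexical-decision MEG study:

* **Design.** Four word conditions x 50 targets, each subject seeing
  every target once, half preceded by related and half by unrelated
  primes; two versions (A/B) swap the assignment and alternate across
  subjects; 200 nonword fillers (75 related / 125 unrelated) exercise
  the screening rules. Item covariates (word length, log surface
  frequency) are drawn per condition from the emulated stimulus-set
  moments.
* **Reaction times.** rt = 620.7 + subject intercept (SD 140) + item
  intercept (SD 50) - priming(condition) x 1[related] + residual
  (SD 100), clipped at 1 ms. Priming defaults are 33.3 / 22.5 / 14.2 /
  14.6 ms (identity / regular / irregular / pseudo-irregular). The SD
  decomposition is chosen so the total (~179 ms) matches the emulated
  study's overall RT SD while the residual reproduces the scale of its
  priming t-values (SE ~7 ms at 800 trials/condition); with those two
  facts fixed there is no freedom left, and a consequence worth knowing
  is that the *ordering* of adjacent condition effects (gaps of 8–11 ms
  vs. an SE of ~10 ms on a difference) is recovered in only ~60% of
  single studies. Accuracy is Bernoulli(0.944), used only by filters.
* **Epochs.** 1000 Hz grid over (-150, +500) ms. Each trial is a smooth
  evoked template (Gaussian components at 100, 170 and 400 ms) scaled by
  (1 + subject gain + item gain), gains N(0, 0.2)/N(0, 0.1); priming
  effects are injected on related trials in configurable latency
  windows as Gaussian bumps (FWHM = window/2; boxcar available for
  oracle tests), optionally scaled per trial by the item's Albright
  score; noise is stationary AR(1) (rho 0.95 at 1 kHz, marginal SD 1.0)
  — autocorrelated noise is what makes cluster-test calibration
  non-trivial, and the single-trial SNR of real source estimates is not
  an observable of the emulated study, so amplitudes are calibration
  choices.
* **Source grid.** A 1-D chain of 30 labeled sources (10 fusiform, 10
  inferior temporal, 10 middle temporal), shared across subjects (no
  inter-subject morphing; a shared grid replaces it). Response signs
  are coherent within an anatomical mask (fusiform +, temporal -),
  mimicking signed free-orientation estimates; only patch sources carry
  the injected effect.
* **Albright scores.** Irregular items from a Beta matched to mean 0.514
  / SD 0.228, regular items from a tight Beta at mean 0.975 / SD 0.025,
  with a Gaussian-copula correlation of 0.29 against log surface
  frequency so orthogonalization is non-trivial. Scores are inputs to
  the analysis; the rule-learning model that produces them is out of
  scope.

Determinism: every component draws from a named substream of the spec
seed, so identical spec + seed give bitwise-identical trial tables and
numerically identical epochs, and adding one component never perturbs
another.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sensor-level physics and artifacts (the
±2.5 pT rejection rule is implemented but exercised on synthetic
raw-mode epochs), right-skewed RT distributions (Gaussian here),
spatially correlated source noise and realistic cortical geometry,
non-stationary noise, and any systematic item-level confound beyond the
induced score–frequency correlation.

## Numerical choices

* Cluster threshold 1.96 (strict inequality), n_perm defaults to 10,000;
  analyses in the test suite and the acceptance script run 200–2,000
  permutations, and simulation studies use 100–200 replicates — sizes
  chosen to keep a full run in minutes on one CPU while leaving the
  Monte-Carlo error well inside the asserted bands.
* Whitened crossproducts are clipped at tiny positive values before
  logs; an RSS that cancels to machine zero (exact fit) yields t = 0.
* Pointwise fits warm-start from the neighboring time point's variance
  ratios; non-converged time points emit 0 and are logged, never
  silently interpolated.
* Baseline correction subtracts the per-trial mean over (-150, -50) ms
  and is idempotent. The low-pass is a 4th-order Butterworth applied
  forward-backward (zero phase; ~48 dB one octave above cutoff), stated
  in attenuation terms so any compliant realization passes the tests.
* JSON reports are serialized with sorted keys; identical config + seed
  reproduce them byte for byte.

## Known limitations

* Random intercepts only; no random slopes or GLMMs.
* Temporal clustering within one ROI only — no spatial or
  spatio-temporal clustering, no TFCE.
* The score-type permutation approximation conditions on observed
  variance ratios; its agreement with exact refits is validated on small
  fixtures, not proven in general.
* Real-data ingestion expects pre-extracted ROI/source time courses
  (delimited text or HDF5); vendor MEG formats and forward/inverse
  modeling are out of scope.
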