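# megprime

Statistical pipeline for masked-priming MEG studies of English past-tense
verbs, built around millisecond-wise crossed random-effects models and
cluster-mass permutation correction — exercised end to end on a synthetic
study generator, so every stage is testable without any recordings.

## Who this is for

Researchers analyzing evoked source-space (dSPM-like) ROI time courses
from priming designs: single-trial amplitudes per subject x item x
condition x prime type, plus lexical-decision reaction times. The package
implements the full analysis chain of such a study — trial/subject
screening, behavioral priming tests, window selection from evoked peaks,
functional-ROI localization, and multiple-comparison-corrected tests of
priming and covariate-interaction effects — and a generator that emulates
the design it targets (16 subjects, four word conditions of 50 targets
each — identity *car–CAR*, regular *jumped–JUMP*, irregular *fell–FALL*,
pseudo-irregular *bell–BALL* — two counterbalanced versions, nonword
fillers).

## The statistics

At every time point *t* of an analysis window, the single-trial amplitude
(or the RT, for the behavioral analysis) is modeled with a Gaussian
linear mixed model with crossed random intercepts,

    y = X beta + Z_s u_s + Z_i u_i + eps,
    u_s ~ N(0, sigma_s^2),  u_i ~ N(0, sigma_i^2),  eps ~ N(0, sigma^2),

where subjects (s) and items (i) are crossed grouping factors and the
fixed effect of interest is PrimeType (related vs. unrelated). Fitting
profiles the (restricted) likelihood over the two variance ratios and
reduces all linear algebra to grouping-factor space via the Woodbury
identity, which keeps thousands of per-timepoint, per-permutation refits
cheap.

Correction over the window follows the cluster-mass max-statistic scheme:
the per-timepoint t-values (|t| > 1.96 forming threshold) are grouped
into maximal runs of one sign, each cluster scored by its mass
Σt, and the largest |Σt| is referred to the null distribution obtained by
relabeling PrimeType **within subject** (preserving each subject's
related/unrelated counts) and recomputing the whole series per
relabeling; Monte-Carlo p-values use the add-one estimator,
p = (1 + #{null max ≥ |Σt|}) / (1 + n_perm). Interactions (e.g.
rule-support score x PrimeType) use the square root of the nested-model
likelihood-ratio chi-square in place of t, with only the A x B pairing
broken under permutation.

The functional ROI is localized on a labeled source grid from an
independent contrast — the facilitatory priming difference (sign-aligned
per source) pooled over the identity and regular conditions — and the
effect is then tested on held-out irregular / pseudo-irregular trials,
so selection cannot bias the test. Rule-support (Albright) scores in
[0, 1] are consumed per item, orthogonalized against log surface
frequency, and tested as continuous interactions or as a high/low split
at 0.5 (strict inequalities; exactly 0.5 is excluded).

## Worked example

```python
from megprime import (AnalysisConfig, generate_design, simulate_rts,
                      simulate_roi_timecourses, exclude_subjects_by_rt,
                      trim_rt_trials, run_behavioral, run_meg_analysis)
from megprime.synth import SimulationSpec

spec = SimulationSpec(seed=1)          # 16 subjects, 50 trials/condition
design = generate_design(spec)
trials = simulate_rts(design, spec)

retained = exclude_subjects_by_rt(trials)          # 2-SD subject screen
clean, log = trim_rt_trials(trials[trials.subject_id.isin(retained)])

cfg = AnalysisConfig(n_perm=2000, seed=1)
behavioral = run_behavioral(clean, cfg)
for cond, block in behavioral["conditions"].items():
    print(f"{cond:17s} priming {block['priming_ms']:5.1f} ms  "
          f"t = {block['t']:.2f}  MC p = {block['mc_p']:.4f}")
print("interaction chi2 = {chi2:.3f}, p = {p:.2f}".format(
    **behavioral["primetype_x_pseudoirregularity"]))

epochs = simulate_roi_timecourses(design, spec)
m170 = run_meg_analysis(epochs, design, "m170_anatomical", cfg)
c = min(m170["result"]["clusters"], key=lambda k: k["mc_p"])
print(f"peak {m170['peak_latency_ms']:.0f} ms, window {m170['window_ms']}, "
      f"strongest cluster {c['start_ms']:.0f}-{c['end_ms']:.0f} ms, "
      f"mass {c['mass']:.1f}, MC p = {c['mc_p']:.4f}")
```

Output:

```
identity          priming  25.0 ms  t = 3.30  MC p = 0.0010
irregular         priming   9.7 ms  t = 1.38  MC p = 0.1609
pseudo_irregular  priming   8.4 ms  t = 1.11  MC p = 0.2529
regular           priming  20.2 ms  t = 2.87  MC p = 0.0060
interaction chi2 = 0.021, p = 0.88
peak 169 ms, window [144.0, 194.0], strongest cluster 170-194 ms, mass 100.5, MC p = 0.0005
```

Reading it: the generator injected priming of 33.3/22.5/14.2/14.6 ms at
the study's noise level; the recovered model estimates (25.0/20.2/9.7/8.4
ms) are attenuated mostly by the 2-SD RT ceiling trim, and identity and
regular priming reach significance at this single-study scale while the
smaller irregular/pseudo-irregular effects do not. The
PrimeType x Pseudo-irregularity interaction is correctly null (the two
effects were simulated nearly equal). In the MEG chain, the detected
evoked peak (169 ms) centers a 50 ms window in which the injected
facilitatory effect forms a cluster at 170–194 ms surviving the 2,000-
permutation max-Σt correction.

The same chains are scriptable from the shell (`megprime simulate`,
`megprime preprocess`, `megprime behavioral`, `megprime meg-anatomical`,
`megprime meg-froi`, `megprime meg-late`, `megprime albright`,
`megprime report`).

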