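# Methods

## The model

`aefactor` analyses patient-level adverse-event (AE) counts pooled
across clinical studies. The unit of analysis is the *AE type* — the
pair of an AE name and its CTCAE severity grade (1 mild … 4
life-threatening), rendered `NAME_severity` (e.g. `VOMIT_2`). Counts
are summarized per *period*: a baseline (pre-treatment) interval or a
treatment interval of one study arm, giving one `N_p x J` matrix
`Y_p` per period over a vocabulary of `J` AE types shared by all
periods.

Each count is Poisson,

    Y_ijp ~ Poisson(C_i * lambda_ij),      lambda = beta + alpha,

where `C_i` is the patient's exposure (the number of treatment cycles;
a single unit for baseline periods) and the intensity splits into a
treatment part `beta` and a study (disease/background) part `alpha`,
with `beta = 0` during baseline. Both parts are low-rank:

    beta = theta . phi        (N x K  .  K x J)
    alpha = xi . eta          (N x L  .  L x J)

`phi` holds `K` treatment-specific occurrence *patterns*; each row is a
probability vector over AE types (a softmax transform), so pattern
intensities are directly comparable across treatments and are reported
in percent. `theta >= 0` is each patient's *safety profile*: a soft
clustering loading saying how much of each pattern the patient
expresses. `eta`/`xi` play the same roles for the study part.
Nonnegativity comes from reparametrization: `theta = exp(theta~)`,
`xi = exp(xi~)`, with the unconstrained loadings kept in a finite box
(default [-15, 15]; `exp(-15) ~ 3e-7` is a numerically zero profile).

Two structural priors encode background knowledge:

- **Mechanism sharing.** Treatments with the same mechanism of action
  produce similar AE patterns, so `phi^(t) = softmax(M^(m_t) + R^(t))`
  row-wise, where `M` is the mechanism's mean-effect matrix and `R` a
  per-treatment random effect. A treatment whose mechanism contains no
  other treatment gets no `R` (the mean and random effect would be
  unidentifiable); this default is configurable.
- **Severity smoothing.** Within one AE name, adjacent severities
  should have similar intensities. Each row of `M`, `R` and `S` (the
  study analogue) carries a Gaussian random-walk (NDLM) prior along the
  chain of *observed* severities of each name, plus a Gaussian anchor
  on the name's lowest observed severity. The anchor both regularizes
  and fixes the translation invariance of the softmax. When a grade is
  never observed (say grades {1, 3} occur but 2 does not), the chain
  links the observed grades directly, keeping every name's chain
  connected.

The joint log-posterior is the Poisson log-likelihood over all periods
plus the NDLM/anchor log-priors on `M`, `R` and `S`. The loadings
`theta~`, `xi~` carry no prior (flat within the box). The `log(Y!)`
constant is included so reported values are true log-probabilities,
comparable across fits.

## Hyperparameters

| name | default | meaning / rationale |
| --- | --- | --- |
| `K` | 15 | treatment patterns; chosen by interpretability, not information criteria |
| `L` | 2 | study patterns; disease-driven AEs are far fewer than treatment-driven ones |
| `sigma_G` | 1.5 | severity random-walk scale; grades span only 1–4 |
| `sigma_M`, `sigma_S` | 5 | anchor scales, wide enough to express any pattern |
| `sigma_R` | 0.5 | treatment random effects ~10% of the mechanism mean effect |

All four scales are fixed hyperparameters, not estimated.

## Estimation

MAP estimation maximizes the joint log-posterior with box-constrained
L-BFGS (`scipy.optimize.minimize`, analytic gradient, `maxcor=20`,
`ftol=1e-12`, gradient tolerance `1e-6`, iteration cap 2000).
Initialization is seeded: pattern matrices start as N(0, 0.1²) noise;
each loading row starts at `log(rate / K)` of the patient's observed
event rate (floored at the lower bound for all-zero rows) plus jitter.

The posterior is multimodal (as NMF-type posteriors generally are), so
`fit_map` supports restarts: `n_restarts` seeded runs, keeping the best
final log-posterior, ties to the lowest seed. One restart suffices for
well-conditioned problems; the recovery experiments use three, which in
our runs eliminated the occasional local optimum where two true
patterns merge.

Row bookkeeping: a patient gets one `theta~` row per treatment ever
received (shared across that treatment's periods) and one `xi~` row per
study, shared across the study's baseline and treatment periods — the
sharing is what lets baseline data identify the study part.

**Pattern ordering.** After the fit, patterns of each treatment are
ordered by their log-probability contribution, operationalized as the
leave-one-pattern-out drop: the log-posterior at the MAP minus its
value with that pattern's loadings forced to the lower bound, all else
fixed. This is deterministic and computable post hoc; the cumulative
share of the ordered contributions supports the usual practice of
reporting the leading patterns that cover 80% of the total increase.
(Single-pattern-addition ordering would be an equally defensible
definition; leave-one-out was chosen because it needs no re-fitting.)

**Pattern matching.** The factorization is identifiable only up to
pattern order, so recovery experiments align estimated rows to a
reference by maximizing total cosine similarity — exhaustively for
`K <= 6`, by Hungarian assignment (also exact) otherwise.

## Fast patient profiles

For a new patient under a treatment with an already-estimated `phi`,
the profile solves

    max_theta~  sum_j log Poisson(y_j | C sum_k exp(theta~_k) phi_kj)

by the same bounded quasi-Newton with analytic gradient. The study term
`alpha` is omitted entirely — for a new patient it is assumed small
relative to the treatment term, and there is deliberately no option to
include it (a new patient has no study loading to share). The default
prior is flat; an optional Normal(mu0, sigma0) prior on `theta~` is
accepted. At `K = 1` the optimum has the closed form
`theta = (sum_j y_j) / C` (each pattern row sums to 1) and is returned
exactly. Re-estimation as AEs accrue can warm-start from the previous
estimate; the optimum is warm-start independent at solver tolerance.

Predicted intensities `lambda_j = sum_k theta_k phi_kj` rank the AE
types to monitor; a severity filter produces the "top severe types"
sub-listing. Report defaults mirror common practice: top 8 types above
1% intensity per pattern plus top 2 severity>=3 types above 0.1%; top
10 / top 10 severe for patient predictions.

## Synthetic data

Real datasets of this kind are access-restricted, so the generator
produces structurally matched data with known ground truth:

- **Design**: arms with a baseline and one or more treatment periods,
  per-period patient counts or dropout fractions (later periods enroll
  thinned subsets). The `table1` preset reproduces a pooled
  three-study design — 10 periods (3 baseline), 5 treatments, 2
  mechanisms, arm sizes 1625/731/480/481 with mid-arm dropout; the
  `recovery` preset is one study, baseline + one 4-cycle treatment
  period, 600 patients, 20 AE names x 3 grades (J = 60), K = 3, L = 1.
- **Patterns**: `M`, `R`, `S` are drawn from the model's own NDLM
  chains used generatively (anchor draw, then a random walk across
  adjacent severities). Generation scales default to anchor 3.0 for
  `M`/`S` (moderately concentrated patterns: a handful of leading
  types, as observed pattern tables typically show), anchor 0.5 for
  `R`, walk step 1.0.
- **Loadings**: a sparse mixture — with probability `pi_zero` (0.6 for
  `theta`, 0.3 for `xi`) the loading sits at the lower bound, else
  `theta~ ~ N(0.4, 0.5²)` and `xi~ ~ N(-1.2, 0.5²)`. This mirrors the
  empirical shape of profile distributions (most patients near zero,
  a few high) and gives the recovery preset roughly ten AEs per
  patient, with the study part contributing well under 10% of events.
  The model itself places no generative law on loadings; this mixture
  is the generator's own choice, exposed in `SimSpec`.
- **Separation**: a configurable fraction of AE names (default 20%) is
  background-only — strongly suppressed (softmax offset -10) in every
  treatment pattern and carried by the study patterns, and vice versa
  for the rest. This makes the treatment/disease separation of the
  model measurable against ground truth.

What the generator does *not* emulate: calendar-time onset and
recurrence dynamics, dose modifications, correlated AE reporting,
MedDRA coding noise, or covariate-driven heterogeneity in loadings.
Passing recovery tests therefore demonstrate that the estimator
recovers the model's own structure at realistic sparsity and sample
sizes — not that real AE data satisfies the model.

## Numerical choices

- Softmax rows use max-subtraction; simplex sums hold to 1e-12.
- Poisson terms treat `lambda = 0` cells exactly: 0 contribution when
  `Y = 0`, `-inf` (flagged by the optimizer with a diagnostic) when
  `Y > 0`.
- The analytic gradient accumulates softmax backprop per treatment
  across its periods before a single pull-back into `M` and `R`;
  agreement with central differences is ~1e-7 relative.
- Ranking ties (equal predicted intensity) break lexicographically by
  label; patient rows within a period follow sorted patient-id order —
  both for determinism.
- Baseline exposure defaults to `C = 1` (one pre-treatment interval);
  configurable, since cycle counts do not apply at baseline. Per-patient
  exposure overrides accommodate mid-period discontinuation.
- Parameter export is a single JSON carrying matrices, row registries,
  adjacency and hyperparameters; floats round-trip exactly, so the
  log-posterior recomputes bit-identically after import.

## Limitations

- `K` and `L` must be chosen up front; no selection machinery is
  provided (information criteria are known to disagree with
  interpretability for this model class).
- MAP only: no posterior uncertainty on patterns or profiles.
- Profile estimation for a patient whose expected total count is small
  is information-limited: with a single pattern, 500 expected events
  put the Poisson error floor at ~4.5% relative; several overlapping
  patterns need a few thousand events for the same accuracy. The
  estimator attains these floors but cannot beat them.
- Dosage differences between studies, within-cycle treatment changes
  and the ordering of AEs within a period are ignored by design.
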