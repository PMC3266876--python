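# Methods

## Model and assumptions

The package models one hermaphrodite's reproduction as mass-action flow
of gametes through compartments:

1. gametes are conserved (`E + S_a + S_d = S0` at all times, with `S_d`
   the cumulative dead sperm and `O_d` dead oocytes in the death variant);
2. every transition is mass action;
3. oocytes are generated at rate `k_g − k_s·O`: constant production
   relaxing toward the gonad carrying capacity `k_g/k_s`. This linear
   saturating form is the minimal choice consistent with a
   carrying-capacity rate constant `k_s`, and it is the form whose
   quasi-steady state gives the Michaelis–Menten egg-laying rate with a
   constant `k_max` and half-saturation `k_hat = k_s/k_o`;
4. ovulation/fertilization is bilinear, `k_o·O·S_a`, reflecting the
   sperm-derived (MSP) signal that couples oocyte maturation and
   ovulation to sperm presence, and consumes exactly one sperm per egg;
5. heat kills sperm at rate `k_d·S_a`; oocyte death is not separately
   identifiable from reduced oogenesis (see equivalence below);
6. egg-laying burstiness is ignored: bursts are minutes apart, far below
   the 2-h and 12-h observation intervals, so eggs are continuous in the
   ODEs and rounded only when counts are reported;
7. `k_max`, `k_d` and the non-robust fraction δ depend exponentially on
   temperature, `exp(a + b·T)`, δ clipped at 1. In the QSS
   parameterization the temperature dependence of the ovulation constant
   is equivalent to a law on `k_max` with `k_hat` held fixed, which is
   how the package states it.

Time zero is the temperature shift at reproductive onset; each animal has
a dead time `t0` before oogenesis starts. The declared validity range of
the temperature laws is 20–30 °C; evaluating outside warns and
extrapolates rather than failing.

### Oocyte death equivalence

Adding an explicit death term `k_do·O` changes the oocyte balance to
`k_g − (k_s + k_do)·O − k_o·O·S_a`, which is the parsimonious model with
`k_s` replaced by `k_s + k_do` (so `k_hat` grows). `with_oocyte_death`
performs the remapping; the egg and sperm trajectories of the two
formulations are identical, which is verified by integration in the
tests. This is why egg-count data cannot distinguish oocyte death from a
lower oogenesis capacity.

### Closed-form (mean-field) solution

The QSS sperm equation `dS/dt = −S·(k_max/(k_hat+S) + k_d)` is separable.
With `A = k_max + k_d·k_hat`,

    F(S) − F(S0) = −t,   F(S) = (k_hat/A)·ln S + (k_max/(A·k_d))·ln(A + k_d·S)
    E(t) = (k_max/k_d)·ln[(A + k_d·S0)/(A + k_d·S(t))]

with the `k_d → 0` and `k_hat → 0` limits handled explicitly, and the
terminal brood `E(∞) = (k_max/k_d)·ln(1 + k_d·S0/A)` → `S0` as `k_d → 0`.
Differences `F(S) − F(S0)` are evaluated with `log1p` in difference form;
the naive antiderivative difference loses all precision when
`k_d·S0 ≪ A` because the prefactor `k_max/(A·k_d)` dwarfs the variation
of the logarithm. `mean_field_solution` solves the implicit relation by
bracketed scalar root finding (brentq) and is the independent oracle for
the numerical integrator; `egg_curve` solves the same relation with a
Newton iteration in `ln S` (the objective is increasing and convex, so
iteration from `ln S0` converges monotonically), vectorized across
animals and times for likelihood work. The two agree to ~1e-12 and the
LSODA integration (rtol = atol = 1e-8) agrees with the closed form to
better than 1e-5 relative error across the tested parameter grid; sperm
counts below ~1e-3·S0 are excluded from relative comparisons because they
sit at the solver's absolute tolerance.

## Synthetic cohorts

The simulator emulates the study design: animals are individually plated,
shifted to the test temperature at reproductive onset, scored
destructively every 2 h for the first 12 h (a fresh set of animals per
time point, so cross-sectional records carry no linkage across times) and
longitudinally every 12 h thereafter until egg laying ceases.

Per-animal heterogeneity:

* one shared standard-normal draw `z` sets `S0 = round(mu_S + sigma_S·z)`
  and `t0 = max(0, mu_t0 + sigma_t0·z)` — sperm count and onset are
  determined by the same variable, giving the observed positive coupling
  between cache size and delayed oogenesis;
* capacity `k_max,i ~ Normal(class mean, sigma_kmax)`, truncated at 0;
  the robust-class mean is the kinetic `k_max` at that temperature, the
  non-robust mean is a fixed fraction of it;
* class is an independent Bernoulli(δ(T)) draw (no coupling between
  sperm count and robustness is assumed);
* counts carry no observation noise beyond integer rounding — eggs are
  counted exactly, and all dispersion is biological plus protocol
  structure.

Default hyper-parameters (calibration choices, all overridable):
`mu_S = 300` sperm with `sigma_S = 45` (brood CoV ≈ 15% at permissive
temperature), onset `4 ± 1.5` h, robust capacity `10 ± 1` eggs/h at
20 °C, non-robust capacity ratio 0.25, `k_hat = 100` sperm. The default
temperature laws are anchored at `k_max`: 10 eggs/h at 20 °C rising to 15
at 29 °C; `k_d`: 0.001/h at 20 °C (negligible; terminal brood ≈ 293 of a
300 cache) rising to 0.25/h at 29 °C (terminal brood ≈ 63 for robust
animals); δ: 0.3 at 28 °C doubling per degree, hence negligible below
26 °C (a smooth exponential, not a hard zero) and saturating at 1 near
30 °C, where reproduction effectively ceases. Negative draws of `S0`,
`t0`, `k_max` are truncated at zero, affecting only far tails. The
default sparse horizon is 180 h, long enough for cessation (last two
counts equal) at every simulated temperature for all but extreme-tail
animals; animals still laying at their final record are excluded from
brood-size summaries with a warning.

What the simulator does **not** emulate: unfertilized-egg laying after
sperm exhaustion, reproductive senescence and declining oocyte quality
beyond sperm depletion, uterine egg retention and the bagging failure
mode, and day-to-day environmental variation between replicate
experiments. Tests passing on these cohorts therefore certify the
inference machinery against the model's own data-generating process, not
against every feature of real egg-count data.

## Likelihood and fitting

The data carry no counting noise, so the observation model is built from
the heterogeneity itself. For a candidate `(mu_kmax, k_d, δ)` each
reproductive class induces a distribution of `E(t)`; its mean and
variance are computed by Gauss–Hermite quadrature (16 nodes over the
shared latent `z`, 8 over the capacity draw) and the class is
approximated as Gaussian with those moments (floored at 0.25 eggs² to
cover rounding and avoid collapse when all sigmas are zero — grossly
off-curve data then incur a large but finite penalty). A cross-sectional
count is scored against the δ-weighted two-class mixture. A longitudinal
animal contributes the increments between consecutive counts (the first
measured from `E(0) = 0`); increments are treated as independent given
the animal's latent class, scored against within-class increment moments,
and the class is mixed at the animal level, preserving class persistence
along a trajectory. Treating one animal's increments as conditionally
independent ignores the within-animal correlation induced by its
continuous latents (`z`, capacity draw); this is a deliberate
approximation that keeps the likelihood closed under quadrature, and the
recovery harness shows the resulting bias on the study design is a few
percent, well inside the quoted tolerances.

Optimization is multi-start Nelder–Mead with rates on the log scale and δ
on the logit scale, bounded (`mu_kmax ∈ [0.5, 100]` eggs/h,
`k_d ∈ [1e-5, 2]`/h, `δ ∈ [0.001, 0.999]`), starts drawn log-uniformly
from a seeded generator; the best of `n_starts` (default 8) is returned
with convergence flags. δ is fitted only above 25 °C by default — at
permissive temperatures it is statistically indistinguishable from zero —
and fixed at 0 otherwise; the temperature-law workflow estimates kinetic
laws from the 20/25/29 °C fits and the δ law from 20/28/29 °C, with
non-positive estimates excluded from the log-linear fit (so in practice
the δ law interpolates the two high-temperature points).

Identifiability: at 20 °C sperm death removes ~2% of the cache, so `k_d`
there carries almost no signal and its estimate can be off by a factor of
a few around a very small value; the recovery harness therefore asserts
`k_d` recovery only at 25 and 29 °C, and recovers capacity within 15% and
δ within ±0.05 at the study's design scale (cohorts of 150–300
longitudinal animals plus dense destructive sampling; the high-temperature
design is the largest, as in the original study). The recovery harness
fits the full generating model (δ free at 25 °C); with δ clamped to zero
there, the few non-robust animals bias `k_d` down by ~10–20%, which is a
model-restriction effect rather than an estimator defect.

## Brood-size distribution analyses

* `infer_sperm_from_brood`: at 20 °C broods ≈ sperm caches, so the brood
  sample's mean and s.d. estimate `(mu_S, sigma_S)`; this parameterizes
  mutant predictions from their measured permissive-temperature broods.
* Mixture fits: `normal+normal` is a common-dispersion two-normal
  mixture (two reproductive strategies with similar within-class spread;
  the shared variance also keeps the likelihood bounded, avoiding
  variance-spike degeneracies of unequal-variance 1-D mixtures);
  `normal+exponential` models robust reproducers plus an exponential
  waiting-time-to-failure component. EM runs to 1e-8 log-likelihood
  tolerance from 10 random restarts plus one start at the single-normal
  solution, which makes the nested fit never fall below the single-normal
  likelihood; a vanished component triggers a restart, and if every
  restart degenerates the single normal is reported. Single-normal
  adequacy is a parametric-bootstrap KS test with parameters re-estimated
  per bootstrap draw (Lilliefors-style; naive KS with estimated
  parameters is anti-conservative). Between one and two components, the
  mixture is preferred only when AIC favors it *and* the bootstrap
  rejects the single normal at 0.05 — AIC alone over-selects mixtures at
  a ~15% rate on normal data, while the combined rule is calibrated. The
  normal+normal vs normal+exponential choice (mechanistically distinct
  interpretations of the non-robust class) is exposed via AIC but not
  auto-decided.
* CoV permutation test: statistic `d = |CoV_A − CoV_B|` (sample s.d.,
  n−1, over mean), group labels permuted over the pooled broods,
  two-sided p as the at-least-as-extreme fraction with the +1
  small-sample correction, so `p ∈ [1/(n+1), 1]`. Sidedness is a package
  choice; 1e6 resamples reproduce the original analysis scale, the
  default is 1e4. No multiple-testing correction is applied, matching
  how the comparisons are reported.

## Problem sizes and numerical defaults

Test-suite simulations use cohorts of 25–300 longitudinal animals and
Monte-Carlo loops of 100–1000 replicates; statistical calibration uses
1000 replicate permutation tests of 1000 resamples each and 100-replicate
mixture-selection loops with 99 bootstrap draws. These sizes were chosen
so each check's Monte-Carlo error is comfortably below the asserted
margin. ODE integration uses LSODA at rtol = atol = 1e-8 with states
clipped at zero; EM tolerance 1e-8; Newton tolerance 1e-13 on `ln S`.
Pipeline outputs embed the configuration, seeds and file hashes in a
manifest, and identical configurations produce byte-identical outputs.

## Known limitations

* The likelihood is moment-matched Gaussian within class, not the exact
  distribution of a rounded nonlinear transform of the latents; its bias
  is quantified only on simulated designs.
* `k_hat` is fixed rather than estimated: egg curves constrain it weakly
  (it only shapes the late, sperm-limited tail), and it trades off
  against `k_max`; fixing it reflects that near-non-identifiability.
* No uterine retention or egg-laying mechanics: at high egg-production
  rates real animals retain embryos and can bag, capping realized broods
  below the model's prediction (the known failure mode for high-sperm
  mutants at 25 °C).
* No Bayesian uncertainty; multi-start MLE with curvature-free
  diagnostics only.
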