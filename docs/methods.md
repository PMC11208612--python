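# Methods

## Sampling model

The package assumes a nested robust design: T primary periods (seasons),
the t-th containing J_t secondary occasions (complete single-day surveys).
The population of marked (individually identifiable) animals is open
between primaries — animals may die, permanently emigrate, or move between
the surveyed area and an unobservable temporary-emigrant state — and open
*within* primaries in the restricted sense that each animal present in a
season enters the surveyed area once, stays for a contiguous run of
occasions, and leaves once (single entry/exit; multiple within-season
entries are outside the model).

### Multi-state open robust design likelihood

States per primary: P (present, observable), E (temporary emigrant,
unobservable), dead (absorbing; apparent death pools mortality with
permanent emigration). Parameters:

| parameter | meaning | units / support | default variation |
|---|---|---|---|
| S | apparent survival per inter-primary interval | probability | constant |
| ψ^{P→E}, ψ^{E→E} | transition to emigrant state, by previous state | probability | per interval (Markovian) |
| pent_t | entry occasion distribution within primary t | simplex over J_t occasions | per primary |
| φ_{t,j} | persistence from occasion j to j+1 | probability | per primary/occasion |
| p | detection per secondary occasion while present | probability | constant |

Within a primary, the availability window [a, d] has probability
pent_a ∏_{j=a}^{d−1} φ_j (1−φ_d), with no departure factor when d = J;
windows partition the unit mass for any valid (pent, φ). The probability
of a within-primary detection vector ω in state P sums over windows
consistent with ω (no detections outside the window) of window mass times
∏ p^{ω_j}(1−p)^{1−ω_j} over occasions inside. Emission probabilities over
all 2^J vectors sum to one (checked exhaustively for J ≤ 4 in the suite).

The likelihood is conditional on first encounter. The primary of first
detection contributes Pr(ω)/p\* — conditioning on at least one detection,
which also fixes the state to P — where p\* = 1 − Pr(all-zero ω | P). Each
later interval applies survival then transition (S first, then ψ; S is
common to both states, since the study treats apparent survival as a
single seasonal quantity), and each later primary emits Pr(ω) in P, an
indicator of the all-zero vector in E, and the same indicator in the dead
state. Unequal calendar gaps between seasons are ignored: S is per
seasonal interval, not per day. The forward recursion over {P, E, dead} is
validated against exhaustive enumeration over latent state sequences ×
availability windows (T = 3, J = 2) to 1e−10.

Estimation is by quasi-Newton (L-BFGS-B) maximisation on link scales —
logit for S, p, φ, ψ; multinomial logit with first-cell reference for each
pent vector — with a deterministic default start plus seeded random
restarts, objective tolerance 1e−8, and finite-difference derivatives
(adequate at the ~10–100-parameter scale of these models). SEs come from
the inverse central-difference Hessian, propagated to the natural scale by
a numerical Jacobian. Boundary estimates (within 1e−4 of 0/1) are flagged;
non-convergence is reported, never silently accepted.

Variation levels follow the field's model notation: `.` (constant),
`season`, `season.day`. For entry probabilities, `season` — one shared
value per cell within a season — collapses to uniform entry under the
sum-to-one constraint (zero free cells); `constant` shares one simplex
vector across seasons (J−1 free cells); `season.day` frees one vector per
season. `psi(Markovian)` is per-interval by default, matching how
transition probabilities are reported per seasonal interval;
`psi(Markovian,constant)` shares one (ψ^{P→E}, ψ^{E→E}) pair, and is what
the recovery harnesses use to keep the parameter count at 10 for the 8×6
design. Random emigration ties ψ^{P→E} = ψ^{E→E} structurally (one free
parameter per interval), so the Markovian family nests it.

Derived quantities: marked abundance N̂_{m,t} = n_t/p̂\*_t (n_t = distinct
individuals detected in primary t), with a delta-method variance from the
fit covariance plus, in the `se_total` variant, the Horvitz–Thompson
binomial component n_t(1−p̂\*)/p̂\*² (both variants are reported, since
conventions differ on including it); transition complements with SEs equal
to the source SEs (the delta method through x ↦ 1−x); and residence time
E[d − a + 1] under the fitted window distribution.

### POPAN super-population likelihood

On season-pooled occasions the full Schwarz–Arnason likelihood is used:
entry proportions pent_t (multinomial logit), survival S_t (logit),
detection p_t (logit), and the marked super-population N on a log scale
offset by the observed count. The combinatorial term ln N!/(N−n)! is
implemented in its Stirling (continuous-N) form N ln N − N − [(N−n)ln(N−n)
− (N−n)], a deliberate numerical choice that makes the N-score equation
exactly N(1−p₀) = n (expected distinct animals detected equals the
observed count at the MLE) and lets the two-occasion case with S = 1 and
first-occasion entry recover the Lincoln–Petersen estimator exactly — both
are tests in the suite. `pent(.)` means one shared per-occasion entry
parameter for occasions 2..T with the first occasion absorbing the
remainder. Fully time-varying structures are flagged: the first/last
detection parameters are confounded with entry/survival. When an
overdispersion adjustment is active, SEs are inflated by √ĉ and ranking
uses QAICc. Only the super-population estimate is carried into downstream
reporting; survival and entry from the open-robust-design model are
preferred since it models the movement process.

### Mark rate and abundance scaling

Two independent ratio estimators of the mark rate θ (the marked fraction
of the population): method 1 pools distinctive-fin image counts over total
quality-image counts across fully photographed groups of more than 20
animals; method 2 pools distinct-individual counts over summed group sizes
across fully photographed groups of at most 20 (where observer counts are
reliable). Both are ratios of pooled totals (equivalently
denominator-weighted means of per-sighting ratios), with binomial SE
√(θ̂(1−θ̂)/n), n the pooled denominator. The combined rate is their
unweighted mean; its SE is not propagated into the total-abundance SE,
which instead uses the binomial term (1−θ)/(nθ) directly with a
caller-supplied n — here the number of distinct individuals identified in
the period being scaled (165, the whole catalog, for the super-population).
That convention is an explicit argument, since the formula's "sample size"
admits several readings; this one reproduces the arithmetic of the
published seasonal table. z is fixed at 1.96.

Rounding: all computation is on unrounded values; the reporting layer
rounds abundances to integers and SEs to one decimal, and confidence
limits are additionally recomputed from the rounded pair, which is how
published tables are usually assembled and the only way their CI digits
can be matched.

## Model selection, GOF, estimability

AICc = −2logL + 2K + 2K(K+1)/(ess−K−1), with the effective sample size
defaulting to the number of capture histories (configurable; rankings at
this scale are insensitive to the convention). QAICc divides the deviance
by ĉ (floored at 1; values above 3 warn of structural inadequacy) and
charges one extra parameter. Akaike weights are exp(−Δ/2) renormalised;
models within 2 units of the best form the averaging window, averaged with
renormalised weights and unconditional SEs √(Σw(se² + (θ̂−θ̄)²)).

ĉ is deviance/df from time-varying CJS fits: per primary over its
secondary occasions, with the global value the ratio of summed deviances
to summed df (a ratio of sums, not a mean of ratios). The CJS deviance is
against the saturated per-cohort multinomial on the reduced m-array; df is
the number of multinomial cells minus one per release cohort, minus the
2(J−1)−1 estimable parameters. TEST2/TEST3 are contingency components on
season-pooled histories — TEST3.SR (newly vs previously marked × seen
again or not), TEST3.Sm (next seen immediately vs later), TEST2.CT (among
animals known alive across an occasion, captured vs not × next capture
immediately vs later) — with columns pooled until expected counts reach 2;
they are calibrated against the χ²/df ≈ 1 null on homogeneous simulations
rather than against any particular software's sub-table construction,
which varies. These tests need the pooled histories themselves, not just
the reduced m-array, because the m-array no longer distinguishes newly
from previously marked animals.

Data cloning refits with every history weighted K times: point estimates
must not move, and the information matrix scales by K, so SEs of estimable
parameters shrink by 1/√K. Both the 1/√K and 1/K reference lines are
reported — descriptions of the expected rate differ in the literature, and
likelihood-information arithmetic gives 1/√K, which is the verdict
criterion (within 25% relative). Boundary parameters are flagged rather
than judged.

## Synthetic data

The generators mirror the fitted processes exactly: per-individual latent
survival/state trajectories, availability windows drawn from (pent, φ),
Bernoulli detections within windows, binomial sighting tallies at a true
mark rate. Defaults reproduce the study conditions — 8 seasonal primaries
× 6 surveys, 165 marked individuals, S = 0.95, p = 0.3 per survey,
Markovian emigration with ψ^{E→E} = 0.55 > ψ^{P→E} = 0.35 (emigrants tend
to stay out, the pattern seen in the field data), entry concentrated on
the first survey day (0.9) with persistence 0.8, giving a residence of
roughly 3.5 of 6 survey days and about 4.5 sightings per detected
individual with ~90% resighted — in the vicinity of the field summary
statistics (≈5 sightings, 81% resighted). The initial state at the first
primary (which the conditional likelihood does not model) defaults to the
stationary P-fraction of the first-interval transition matrix and is
configurable. All individuals exist from the first primary: the MSORD
likelihood conditions recruitment away, so staggered recruitment is
simulated only for the POPAN generator (entry multinomial over occasions).

What the generators do **not** emulate — and what passing tests therefore
do not establish about field data: individual heterogeneity in detection
or survival, group-structured (non-independent) detection within
sightings, multiple within-season entries, misidentification, and mark
change. Recovery results certify the estimators under the model's own
assumptions, not robustness to their violation.

Simulation scales were chosen to keep the full validation suite at
workstation scale: single-fit checks use 120–500 individuals; the recovery
experiment uses 100 replicates of 165 individuals on the 8×6 design with
the 10-parameter constant-ψ Markovian structure; data cloning uses K =
100. Every stochastic routine takes an explicit seed and is a pure
function of (parameters, seed).

## Known limitations and numerical notes

* Maximum-likelihood estimates at the study scale carry small
  finite-sample bias; in the recovery experiment at 165 individuals the
  detection probability shows a bias of about +0.01 (3% relative, with
  nominal Wald coverage), which vanishes by n = 2000. Survival and
  transition estimates are unbiased to Monte-Carlo resolution.
* The likelihood conditions on the first-encounter primary via division by
  p\*; whether a given software package uses the identical conditioning
  convention is not assumed anywhere — correctness is established by
  simulation, and criterion-level numerical equality with other
  implementations' AICc values is not claimed.
* Negative `.inp` frequencies (losses on capture) are rejected; the
  sampling design has none.
* Finite-difference Hessians can be indefinite near boundaries; such fits
  carry a message and their SEs should not be trusted (data cloning flags
  the affected parameters).
* At most two geographic states, no dead recoveries, no individual
  covariates; "season.day" variation frees one parameter per cell subject
  to the structural constraints (pent: J−1 per season; φ: J−1 per season).
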