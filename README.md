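# spinnerpop

Open-population capture–recapture estimation of abundance, apparent
survival and temporary emigration for photo-identified dolphin
populations, built around the study design used for island-associated
spinner dolphins: seasonal primary periods each containing several
single-day surveys (a robust design), with individuals identified from
distinctive dorsal-fin marks.

It is written for population ecologists who have capture histories from a
nested primary/secondary survey design and want the full inference chain —
likelihood fitting, model selection, goodness-of-fit, and scaling from the
marked fraction to total abundance — in one scriptable Python package.

## The models

**Multi-state open robust design (MSORD).** Marked animals move between an
observable state *P* (present in the study area) and an unobservable
temporary-emigrant state *E*. Between primary periods an animal survives
with apparent survival *S* and transitions with Markovian probabilities
ψ^{P→E}, ψ^{E→E} (random emigration ties the two, "no emigration" fixes
both at 0); complements are derived by subtraction, e.g. ψ^{E→P} = 1 −
ψ^{E→E}. Within a primary of *J* secondary occasions, an animal in state
*P* enters the area once at occasion *a* with probability pent_a, persists
occasion-to-occasion with probability φ_j, leaves once, and is detected
with probability *p* while present (capture equals recapture probability —
photo-identification provokes no trap response). The availability window
[a, d] has mass

    pent_a · ∏_{j=a}^{d−1} φ_j · (1 − φ_d)    (no departure factor at d = J),

and the likelihood is conditional on first encounter: the first detected
primary contributes Pr(ω)/p\*, with p\* the probability of ≥1 detection for
a present animal; later primaries run a forward recursion over {P, E,
dead}. Marked abundance per primary is derived as N̂_m = n/p̂\* with a
delta-method SE.

**POPAN (Jolly–Seber super-population).** Captures pooled within seasons;
animals enter the marked population with probabilities pent_t summing to
one, survive with S_t, and are detected with p_t. The full
(Schwarz–Arnason) likelihood including the never-detected fraction
estimates the super-population N of marked animals using the study area at
any point during the study.

**Scaling to total abundance.** Capture histories cover only the
distinctively marked fraction θ (estimated two independent ways from group
sightings: the proportion of quality images showing distinctive fins in
large fully photographed groups, and distinct individuals over summed
group sizes in small groups). Totals follow

    N̂_total = N̂_m / θ̂,
    SE(N̂_total) = sqrt( N̂_total² ( SE(N̂_m)²/N̂_m² + (1−θ̂)/(nθ̂) ) ),

with log-normal 95% limits (N̂_total/C, N̂_total·C),
C = exp(1.96·sqrt(ln(1 + (SE/N̂_total)²))).

Model selection uses AICc (QAICc with a deviance/df overdispersion factor
ĉ), Akaike weights and 2-unit model averaging; goodness-of-fit uses
per-primary CJS deviance/df and RELEASE-style TEST2/TEST3 contingency
components; parameter estimability uses data cloning (SEs of estimable
parameters shrink by 1/√K when the data are cloned K times).

## Worked example

```python
import spinnerpop as sp

# seasonal abundance: 89 marked animals (SE 3.5), 72 identified, theta = 0.30
N = sp.total_abundance(89, 0.30)                      # 296.67 -> 297
se = sp.total_abundance_se(89, 3.5, 0.30, n=72)       # 54.7
lo, hi = sp.lognormal_ci(297, 54.7)                   # (207.6, 424.8)

# fit the MSORD to simulated study-scale data (8 seasons x 6 surveys)
design = sp.study_design()
truth = sp.study_truth(design)                        # S=0.95, p=0.3, ...
matrix, _ = sp.simulate_msord(truth, design, 165, seed=42)
structure = sp.ModelStructure(s="constant", p="constant", pent="constant",
                              phi="constant", emigration="markovian",
                              psi_time=False)
fit = sp.fit_msord(matrix, structure)
print(fit.natural_estimates()["S[1->2]"])             # 0.959 (SE 0.020)
```

The scaled estimate reads: about 297 dolphins (SE 54.7) used the study
area that season, with 95% confidence between 208 and 425; the fitted
apparent survival 0.959 ± 0.020 recovers the generating value 0.95.

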