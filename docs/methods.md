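# Methods

## Model structure

The hematopoietic system is a directed chain of cell compartments updated
synchronously in discrete time. Common-precursor stages are indexed
`k = 0..K_C`, with stage 0 the stem-cell pool. Each committed lineage
`x ∈ {E, G, T}` (erythrocytes, granulocytes, thrombocytes) has stages
`k = 1..K_x`; the last stage is the circulating blood pool, every other
compartment is bone marrow. The *global* stage index is `j = k` for common
stages and `j = K_C + k` for committed ones, so differentiation progress
is measured on one axis shared by all lineages.

### Stochastic update

For a compartment of `N` cells dividing at rate `r` (per day), the number
of cells leaving within one step of length `dt` is

    M ~ Binomial(N, r·dt).

Migrating cells divide on exit: the downstream compartment gains `2M`.
Two exceptions: the stem pool divides asymmetrically (one daughter stays,
one moves on, so stage 1 gains `M` undoubled and the stem count is
constant at `N_S`), and the last thrombocyte division fragments into
`m_T = 50` platelets. The outflow of the last common stage is split over
the three lineages with a multinomial draw at the commitment
probabilities `q_x`. Blood pools have no downstream compartment; their
"outflow" is cell death at constant rate `r_x`.

With overdispersion `γ > 0`, the per-step division probability is drawn
per compartment as `P ~ Beta(α/γ, (1−α)/γ)` with `α = r·dt`, which
preserves the mean `E[M] = N·r·dt` and interpolates continuously to the
plain binomial as `γ → 0`. The default noisy setting is `γ = 0.03`.

### Rate laws

Receptor occupancy is logistic in the global stage,
`p_x(j, c) = 1/(1 + exp(−(a_x·j + b + c_x)))`, with one shared offset `b`
and per-lineage slopes `a_x`. Division rates:

- common stage `k`: `r_max·(1 − Π_x (1 − p_x(k, c)))` — divide if any
  receptor is occupied;
- committed marrow stage `k` of lineage `x`: `r_max·p_x(K_C + k, c)`;
- blood stage: constant death rate `r_x`.

Commitment weighs simultaneous occupancies at the last common stage
symmetrically — a cell with only factor `x` bound commits to `x`; with
one competitor also bound, with probability 1/2; with all three bound,
1/3 — and the three weights are normalized.

Feedback: each growth-factor log-concentration is linear in the relative
deviation of its blood count from target, `c_x = δ·(N_x − count_x)/N_x`,
evaluated from the pre-step counts.

## Calibration

All free parameters follow from clinical anchors: `N_S = 400`,
`N_E = 2.5×10^13`, `N_G = 2×10^10`, `N_T = 1.25×10^12` (250 000/µL in
5 L of blood), initial lifetime guesses `1/r = 110/2/10` d, `m_T = 50`,
`r_max = 5`/d, stem rate `r_S = 1/365`/d, last-marrow-stage rate
`r_blood = 4`/d, and a CFU-GEMM pool target of 60 000 cells.

1. `b`: at the stem stage all three occupancies are equal, so
   `r_S = r_max·(1 − (1 − p)^3)` inverts to
   `p_stem = 1 − (1 − r_S/r_max)^{1/3}` and `b = logit(p_stem) ≈ −8.61`
   (taking the stem stage as `j = 0`).
2. `a_x`: the last marrow stage `j = K_C + K_x − 1` divides at `r_blood`,
   so `a_x = (logit(r_blood/r_max) − b)/(K_C + K_x − 1)`.
3. `K_x`: at the conditional steady state every stage doubles its
   expected daily outflow, so the blood balance
   `N_x·r_x = N_S·r_S·2^{K_C+K_x−1}·q_x·m_x` gives
   `K_x = 1 − K_C + log2(N_x·r_x/(N_S·r_S)) − log2(q_x) − log2(m_x)`.
4. Since `a_x` depends on `K_x` and `q_x` on `a_x`, steps 2–3 iterate
   from `q_x = 1/3` to a fixed point (converges in 15 iterations to
   ~1e-10). Stage counts are then rounded to the nearest integer
   (half away from zero), slopes and commitment probabilities are
   recomputed, and the blood balance is re-solved for the death rates:
   adjusted lifetimes `1/r_E = 104.41` d, `1/r_G = 1.62` d,
   `1/r_T = 11.20` d, making the blood targets exact by construction.
5. `K_C` is selected by scanning candidates and fitting the full model
   for each: the conditional steady state fixes the last common pool at
   `N_C = N_S·(r_S/r_C)·2^{K_C−1}`, and `K_C = 14` comes closest to the
   60 000-cell CFU-GEMM anchor (`N_C ≈ 60 171`).
6. `δ`: demanding that a fully depleted lineage (`c_x = δ`) push the stem
   stage to `r'_S = 1.00`/d gives `δ = logit(p'_stem) − b ≈ 6.05`.

The resulting chain is 41 divisions from stem cell to erythrocyte, with
amplification `2^40·q_E ≈ 2×10^11` per stem-cell division.

## Steady state and initialization

Conditional on fixed concentrations, expectations propagate in closed
form: `E[M]` doubles per stage down the chain and `E[N] = E[M]/(r·dt)`
per compartment. Simulations start from these expectations rounded to
integers, with the blood pools pinned to their exact integer targets
(the adjusted death rates make those expectations exact). The marrow
total at target is ≈ 6.9×10^10 cells (≈ 14 000/µL of blood volume),
roughly half the marrow capacity used by the mutation extension.

## Mutations and marrow overflow

Every non-stem cell may divide at most `R = 60` times (Hayflick limit);
for healthy cells the divisions already used equal the global stage, so
only mutant cohorts track an explicit remaining capacity. Mutant cohorts
are keyed by (lineage, stage, mutation flags) with an integer vector over
remaining capacity; they divide at the same stage rate, under the same
overdispersion, as healthy cells. A *differentiation block* keeps both
daughters at the parent's stage and burns one capacity unit; cells at
capacity 0 vanish when sampled to divide. *Unlimited replication* stops
the capacity decrement. Their combination doubles in place indefinitely.

The marrow holds at most 30 000 cells/µL × 5×10^6 µL = 1.5×10^11 cells.
When an update exceeds this, the excess is removed uniformly at random
across *all* marrow compartments — healthy and mutant, the stem pool
included — and reported as circulating blasts. Including the stem pool is
a deliberate design choice: it makes a marrow fully taken over by blasts
extinguish hematopoiesis permanently (blood counts collapse and stay
down), whereas a protected stem pool would regenerate the system after
the clone burns out. The base engine (no mutations) never reaches the
capacity, so its stem-count invariant is unaffected.

Analytic timeline: while the clone is small the blood counts are
unperturbed, so a block+immortal cohort founded at global stage `j` grows
in expectation as `exp(r_j·t)` at the `c = 0` stage rate `r_j`. Time to
diagnosis (clone = half the healthy marrow total) from one founder at
`j = 1` evaluates to ≈ 18.3 years; diagnosis (half) to breakdown (twice
the marrow) takes `ln 4 / r_j ≈ 1` further year — fast progression after
a silent couple of decades.

## Numerical choices

- `dt = 0.04` d by default (`1/(5·r_max)`, five steps per fastest
  expected division); multi-year leukemia runs use `dt = 0.2` d, the
  largest step with `r_max·dt ≤ 1`. Validation rejects `r·dt > 1`.
- Counts are 64-bit integers throughout; binomial sampling handles the
  10^13-cell blood pools directly.
- The uniform marrow push-out is a multivariate hypergeometric draw,
  realized as sequential conditional draws. Each conditional marginal
  uses the exact hypergeometric sampler when population sizes permit
  (< 10^9, a limit of the underlying generator) and a clipped binomial
  approximation of it otherwise; the removal is exactly mass-conserving
  and feasible in both branches. At marrow scale (10^11 cells) the
  binomial approximation's relative error is negligible.
- One generator instance drives an entire run; every simulation is
  bit-for-bit reproducible from its seed, and the mutation stepper
  consumes draws in the same order as the base engine, so with no
  mutation events the trajectories are identical draw for draw.

## Known limitations

- In a year-long closed-loop run without overdispersion, the
  time-averaged relative deviation of blood counts from target is seed
  dependent at 0.04–0.16% (worst lineage). The counts execute a slow
  wander with a correlation time of weeks: shot noise injected high in
  the cascade is amplified ~2^40-fold and only weakly damped by the
  feedback (doubling `δ` roughly halves the deviation). The deviation of
  the *year-long mean* from target is considerably smaller than the mean
  absolute deviation; the two statistics should not be conflated.
- Overdispersion (`γ = 0.03`) widens the band roughly tenfold and
  introduces a small systematic offset, granulocytes being most affected
  (shortest-lived pool, strongest relative noise).
- The model has no explicit cell age, space, or niche structure;
  compartments are well mixed, and the marrow capacity is a single hard
  global constraint.
- The analytic leukemia timeline ignores capacity limits and feedback
  perturbations; it describes the pre-clinical growth phase only.
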