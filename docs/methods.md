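# Methods

## Model

The extended model couples three per-km² state variables: the stock `R` of a
habitat-forming, harvestable foundation species (resource units km⁻²), the
human population density `P` (people km⁻²), and species richness `S`
(species).

```
dR/dt = c0 R (1 − R/K_max) − h P                     (logistic growth, linear harvest)
dP/dt = r P (1 − P / (q·ES(S)))                      (logistic growth toward a service-based capacity)
dS/dt = d (S_eq(R) − S)                              (relaxation toward the species–area equilibrium)
```

with the saturating links

```
ES(S)   = ES_max · S / (c1 + S)                      (biodiversity → ecosystem services)
S_eq(R) = S_max · R / (c2·K_max + R)                 (species–area relationship)
```

Assumptions: open-access harvesting proportional to population; a
non-substitutable service bundle with equal per-species contributions;
habitat area proportional to the foundation-species stock; deterministic,
autonomous mass-action dynamics; no imports, technology dynamics or
governance feedbacks. Units follow the per-km² calibration throughout; the
system is never nondimensionalized.

Two control variants isolate the role of the debt:

* **baseline** — `dP/dt = r P (1 − P/(q R))`: the population is limited by
  the resource directly; no biodiversity state.
* **quasi-static (no-debt)** — `S ≡ S_eq(R)` substituted into `ES`: the
  `d → ∞` limit in which biodiversity tracks habitat instantaneously, so
  extinction debts and immigration credits never exist.

### Parameters (defaults)

| symbol | meaning | unit | default |
|---|---|---|---|
| r | human population growth rate | yr⁻¹ | 0.0044 |
| q | people per service unit | — | 1 |
| ES_max | maximum service supply | service units km⁻² | 700 |
| c1 | richness at half-maximum services | species | 100 |
| c2 | relative area at half-maximum richness | — | 0.2 |
| c0 | resource productivity | yr⁻¹ | scan 0–0.044 |
| K_max | resource carrying capacity | resource units km⁻² | 700 |
| d | biodiversity relaxation rate | yr⁻¹ | ln2/50 |
| S_max | maximum richness | species | 1000 |
| h | per-capita harvest rate | resource units person⁻¹ yr⁻¹ | scan 0–0.0132 |

`d = ln2/50` is a 50-year half-life for debt repayment, so half of a debt is
paid in 50 years and 99% in `−ln(0.01)/d ≈ 332` years
(`relaxation_time`). `c0` and `h` are the scanned control axes; the
`ModelParams` defaults pin `c0 = r` and `h = 0` and every analysis takes
explicit overrides.

### Functional-form registry

The two links are pluggable. Besides the default saturating forms the
registry ships two stand-ins used for robustness checks — exponential
service saturation `ES_max(1 − exp(−S ln2/c1))` (same half-maximum) and the
classic power-law species–area curve `S_max (R/K_max)^z`, `z = 0.25` by
default. They are qualitative stand-ins, not calibrated alternatives. Each
entry carries its derivative so the analytic Jacobian works for every form;
non-default forms switch equilibrium location from the closed form to
grid-seeded bracketed root-finding (1000 brackets, Brent refinement).

### Regularization at vanishing services

`dP/dt` divides by the carrying capacity `q·ES(S)` (and `q·R` in the
baseline), which vanishes at `S = 0` (`R = 0`). The divisor is floored at
`SERVICE_FLOOR = 1e−9` people km⁻², keeping `dP/dt` strongly negative but
finite when services collapse; collapse dynamics are preserved and the ODE
stays integrable. The analytic Jacobian refuses states at the floor (the
expression is invalid there); the origin is classified with the floored
divisor treated as constant.

## Equilibria and stability

Eliminating `S* = S_eq(R*)` and `P* = q·ES(S*)` reduces the steady state to
`c0 (1 − R/K_max)(C + D R) = B` with `C = c1 c2 K_max`, `D = c1 + S_max`,
`B = h q ES_max S_max` — a quadratic solved exactly. Roots are kept on
`(0, K_max]`; roots closer than `1e−9 K_max` merge into the fold's double
root. An independent brute-force oracle (`interior_root_scan`) locates the
same roots by sign changes on a 10⁵-point grid and backs the closed form in
the tests.

Stability is numeric: eigenvalues of the analytic Jacobian, with
`|Re λ| ≤ 1e−9 yr⁻¹` labelled *marginal* (below eigen-solver noise at these
magnitudes). Records are only emitted with right-hand-side residuals below
`1e−8` state-units yr⁻¹. The extended Jacobian has three structural zeros
(`∂Ṙ/∂S`, `∂Ṗ/∂R`, `∂Ṡ/∂P`): harvest does not see biodiversity, population
growth sees habitat only through services, and richness does not see
people.

A consequence worth noting for the baseline control: its interior
equilibrium `R* = K_max(1 − hq/c0)` is feasible for `hq < c0` but stable
only while the Jacobian trace `2hq − c0 − r` is negative; beyond that it is
an unstable spiral. The baseline safe set used in comparisons is therefore
`hq < c0` **and** `2hq < c0 + r`.

## Fold and exit loci

Because `B` is linear in `h`, the fold (tangency) condition gives a straight
locus `h_fold(c0) = c0 (1 − R_m/K_max)(C + D R_m) / (q ES_max S_max)` with
the fold's resource coordinate `R_m = K_max/2 − C/2D` independent of `c0`
and `h` (343.64 for the defaults; slope 0.28509). The unstable root leaves
the feasible region through `R = 0` at `c0_exit = B/C = 50 h` (defaults),
i.e. 150·r at the maximum scanned harvest rate — the system is bistable for
`c0_fold(h) < c0 < c0_exit(h)`. Degenerate parameter sets with `R_m ≤ 0`
fall back to a numeric maximization of the supply curve. Branch diagrams
report `c0` both raw and in multiples of `r`, and encode infeasible branch
segments as NaN gaps, never zeros.

## Numerical integration

Adaptive Dormand–Prince RK45 (`scipy.integrate.solve_ivp`), defaults
`rtol = 1e−8`, `atol = 1e−10`, `max_step = 1` year, reporting grid
`Δt = 1` year. Long-horizon diagnostics (ghost passages, basin mapping)
lift `max_step` and report the solver's natural accepted steps — the
dynamics there are slow and smooth, and the error control alone sets the
step. Runs terminate by default when `R` or `P` crosses the collapse floor
`1e−3` km⁻² units; this both defines the collapse outcome and keeps
trajectories inside the non-negative orthant (past exhaustion the harvest
term would otherwise drive `R` negative). Negative undershoot beyond
`10·atol` raises. Self-convergence (halving tolerances) is asserted in the
tests at `1e−6` relative on collapse trajectories.

Outcome classification: *sustainable* if the final state is within 1%
relative distance of a feasible stable equilibrium; *collapse* at/below the
floor; otherwise *undecided* — a run that merely looks flat (e.g. near a
ghost) is never promoted to sustainable.

## Safe-operating-space mapping

Existence and stability of the sustainable equilibrium are decided
analytically per `(c0, h)` cell; basin fractions by forward integration
from a deterministic 21×21 grid of initial states over
`R ∈ [0.01 K_max, K_max] × P ∈ [1, q·ES_max]`, with `S` started on the
debt-free manifold `S_eq(R)` (an optional third axis samples
`S ∈ [0, S_max]`; optional Latin-hypercube sampling takes an explicit
seed). Region labels: **III** no sustainable equilibrium (basin 0), **I**
every sampled state converges, **II** otherwise. Basin runs use
`rtol = 1e−6`, an early-stop event at 0.5% relative distance from the
target equilibrium, and a 20,000-year horizon (~88 population-growth time
constants, far beyond observed ghost transients at the default scan
resolution); undecided fractions above 5% warn. The default map grids
(45 productivity × 33 harvest cells) exclude the degenerate `c0 = 0` and
`h = 0` boundary lines, where classification is trivial (universal collapse
and unconditional sustainability respectively). Basins are estimated by
forward integration only; separatrix surfaces are not computed.

## Ghost-attractor diagnostics

Just below the fold (`c0 < c0_fold(h)`) the vanished equilibrium leaves a
slow region around the fold-point state
(`R_m, q·ES(S_eq(R_m)), S_eq(R_m)`) — the *ghost*. `ghost_transit_time`
integrates from the ghost (or a supplied start) and accumulates the time
the trajectory spends within a relative-distance ball (default 10%,
Euclidean norm relative to the ghost's norm), with crossings interpolated
linearly between natural solver steps. Transit times follow the fold's
slow-passage law `T ∝ (c0_fold − c0)^{−1/2}`; the test suite fits the
log–log slope over `ε ∈ [10⁻⁵, 10⁻³]·c0_fold`.

The per-interval speed metric on uniform reporting grids is
`log(1 + (|ΔP| + |ΔR| + |ΔS|)/Δt)` — absolute per-year changes summed, the
logarithm compressing the fast collapse phase so slow passages stay visible
on one scale. On ghost passages the speed minimum sits on the ghost (within
5% in the tests).

## Perturbation experiment

At `t_pert` a fraction `φ` of the resource stock is removed instantaneously;
`P` and `S` are continuous across the jump — habitat loss precedes
extinctions, which is precisely what creates the debt
(`S > S_eq((1−φ)R)`). The unperturbed counterfactual is integrated with the
same two-leg protocol (restart at `t_pert` without jump), so a null
perturbation reproduces it bitwise; the experiment requires the
counterfactual to be sustainable. The quasi-static variant runs under the
identical protocol as the no-debt control. Annotations: *initial recovery*
is the interval from the jump to the first post-jump local maximum of `R`
(present only if `R` rises immediately after the jump); *collapse onset* is
the first time `R` falls back below its post-jump value after the recovery
peak (or below half the pre-perturbation level when there is no recovery).

The package ships a grid-search routine (`find_reversal_case`) over the
bistable wedge (`c0 ∈ [r, 10r]`, `h` between the exit and fold loci,
`φ ∈ [0.3, 0.9]`, colonization-style starts perturbed while the population
is still growing) and pins the found instance as `REVERSAL_FIXTURE`:
`c0 = 10r`, `h` at 90% of the way from exit to fold, a debt-free start
`(0.95·K_max, 50, S_eq)` perturbed at year 400 with `φ = 0.9`. There the
extended model recovers for ~90 years and then collapses while the no-debt
variant returns to equilibrium. The qualifying window is narrow — the debt
changes the outcome only near the basin boundary — which is why the pinned
fixture, not a re-search, backs the regression test. The reversal is
one-directional by construction: under identical perturbations the debt can
convert sustainable into collapse, never the converse, since the
quasi-static capacity `ES(S_eq(R))` always upper-bounds the extended
capacity during a dip (`S` lags above `S_eq` only transiently).

## Interfaces and determinism

Parameter sets and run configurations are flat YAML with keys named after
the model symbols; unknown keys fail fast (pydantic, `extra="forbid"`).
Every run writes a resolved-config copy and a SHA-256 manifest next to its
artifacts; floats serialize with 17 significant digits and CSVs are read
back with the round-trip parser, so serialization is lossless and repeated
runs are bit-identical. Figures are drawn only from the CSV artifacts and
can be regenerated from disk (`sesdebt figures`).

## Problem sizes in the shipped tests

The test suite exercises scaled-down instances chosen to keep the whole
suite in the tens of seconds while leaving every mechanism intact:
safe-operating-space checks use a 6×5 `(c0, h)` grid with 5×5 initial
states (the region structure is already stable at that sampling, as the
resolution-doubling test asserts); oracle cross-checks use 50–200 random
parameter draws; ghost scaling uses 7 ε-values over two decades. Full-size
maps (45×33 cells, 21×21 starts) are what the library defaults produce and
take correspondingly longer.

## Known limitations

* Basin fractions are sampling-based; no separatrix computation.
* The alternative functional forms are documented stand-ins.
* No stochastic forcing, demographic structure, imports/exports, adaptive
  governance or early-warning indicators; the model is a minimal,
  deterministic caricature whose value is conceptual, not predictive.
* The regularization floor makes the origin's stability classification an
  artifact of the floored dynamics (physically, collapse trajectories
  approach it asymptotically).
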