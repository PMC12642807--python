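# Methods

## The model

`symbiovade` implements a consumer–resource model of two host populations
(native `p_n`, invasive `p_i`; think plants) coupled to their microbial
symbiont communities (`m_n`, `m_i`; think mycorrhizal fungi) through explicit,
density-dependent resource exchange. Hosts are facultative mutualists with
intrinsic growth rate `r_p`; symbionts are obligate and have no intrinsic
growth term. Each compartment `x` follows

    dx/dt = [growth] + [net exchange flux] − [interspecific competition] − μ x²

The exchange fluxes are sums of saturating kernels. Symbiont-*j* → host-*k*
supply is `α_jk · m_j · p_k / D_α` with the shared denominator
`D_α = (p_n + p_i)/d + m_n + m_i`, and host-*j* → symbiont-*k* supply is
`β_jk · p_j · m_k / D_β` with `D_β = p_n + p_i + d·(m_n + m_i)`. Subscript
convention everywhere: **first index = supplier, second = receiver**. The
denominators make every transfer limited by the partner of lower biomass,
with the dimensionless factor `d` setting the host↔symbiont biomass
exchange ratio. Each aggregate flux is a conversion efficiency `q` times the
sum of its kernels, so the per-pair conservation identity — what host *j*
pays along `β_jk`, per unit `q_cp_j`, is exactly what symbiont *k* receives
per unit `q_cm_k` — holds structurally, and the test suite verifies it to
machine precision.

All flux ratios are defined as 0 when their denominator is 0. With `d > 0`
that happens only at the all-zero state, so total extinction is always an
equilibrium.

## The mutualism–parasitism continuum

For a single host–symbiont pair the system collapses to two equations in
which the whole interaction enters through two signed coefficients:

    Q_p = q_hp·α/d − q_cp·β        (net effect of the symbiont on the host)
    Q_m = q_cm·β − q_hm·α/d        (net effect of the host on the symbiont)

with interaction term `s = p·m/(p/d + m)`. Signs classify the association:
(+,+) mutualistic, (−,+) parasitic for the host, (+,−) parasitic for the
symbiont; a coefficient within 1e-12 (absolute) of zero is treated as a
commensal boundary, and (0,0) as neutral. The boundary patterns (0,−) and
(−,0), which sit between a parasitic region and the double-negative region,
are classified by the harmed partner.

Two conventions deserve explicit statement:

- **The double-negative pattern.** (Q_p<0 and Q_m<0) is reported as
  `invalid_exchange` rather than placed on the continuum. It is *attainable*
  for strictly positive efficiencies: whenever `q_hp/q_cp < q_hm/q_cm` there
  is a band `(q_hp/q_cp)·α/d < β < (q_hm/q_cm)·α/d` in which both partners
  lose from the exchange. Because the canonical taxonomy has no such region,
  the package flags it instead of silently labelling it.
- **`d` and the reduced system.** The two-species reduction used for regime
  classification takes its (α, β) verbatim from the full model, which is what
  the region-boundary lines `α = (q_cp/q_hp)·d·β` and `β = (q_hm/q_cm)/d·α`
  assume. The *exact* dynamical restriction of the four-compartment fluxes to
  one pair corresponds instead to the reparametrization `α → d·α, β → β/d`
  (the two coincide at `d = 1`, the package default). `pair_params` gives the
  former (regime algebra), `reduced_from_full` the latter (dynamics); the
  restriction-equivalence tests hold exactly for every `d` through that
  mapping. Note the sign of `d·Q_p` is invariant under the mapping’s scale
  factor only at `d = 1`; at `d ≠ 1` regime calls should always go through
  `pair_params`.

Cross-community edges (`p_n`↔`m_i`, `p_i`↔`m_n`) define the canonical
invasion scenarios: ① no shared partners; ② / ③ a mutualistic cross edge
(native symbionts with invasive hosts / invasive symbionts with native
hosts); ④ / ⑥ the cross edge parasitic for the host; ⑤ / ⑦ parasitic for the
symbiont. When both cross edges are active the label is the ordered pair of
per-edge digits, e.g. `(2,6)`.

## Numerics

- **Integration.** `scipy.integrate.solve_ivp` with LSODA at `rtol = 1e-9`,
  `atol = 1e-12`. These are deliberately tight so that the extinction
  threshold (1e-6 relative) sits orders of magnitude above solver noise and
  outcome labels are reproducible. Trajectory components are clipped to zero
  from below on output; an excursion beyond −1e-9 is treated as a solver
  failure, not noise. An independent fixed-step classical RK4 integrator
  (numba-compiled for the reduced system) serves as a cross-check; adaptive
  and fixed-step routes agree to ~1e-8 relative at t = 100 on random
  mutualistic pairs.
- **Equilibria.** `scipy.optimize.root` (hybrid Powell) with the analytic
  Jacobian — the fluxes are rational functions, so exact partial derivatives
  are available everywhere except the origin, where one-sided finite
  differences are used. Reported equilibria have residual below 1e-9.
  Stability is read off the Jacobian eigenvalues with a ±1e-10 margin;
  boundary equilibria with an extinct obligate symbiont are *linearly
  marginal* (the symbiont decays only quadratically, −μm², so its eigenvalue
  is exactly 0) even though they are nonlinearly attracting.
- **Convergence detection.** Runs terminate early when `||RHS||_∞ < 1e-10`,
  with a hard cap of 1e5 time units. If the cap is reached and any component
  ranges over more than 1e-6 in the final window (length 1e3), the run is
  flagged as a limit cycle and the window time-average is reported — always
  with the flag, since the outcome taxonomy assumes point attractors.

## Invasion experiments

The resident (native) pair is integrated from a generic positive state to its
attractor and polished by Newton iteration; a host-only equilibrium is a
valid resident (an obligate symbiont with `Q_m ≤ 0` goes extinct), and an
error is raised only if the whole resident community collapses. The invader
is introduced at 1e-3 of resident total biomass (split equally over the
introduced compartments) — small enough for linearized invasion criteria to
apply, three orders of magnitude above the extinction threshold. Endpoints
are thresholded at ε = 1e-6 × resident total biomass, and the 16 persistence
patterns map to named outcomes (native resistance, co-invasion, full
coexistence, host invasion retaining native symbionts, …; unnamed patterns
carry a `collapse_or_partial_` tag). Extinction pathways record, per
compartment, the earliest threshold down-crossing with no later recovery, at
the resolution of the solver's output grid; transient dips are never
reported as exclusions.

## Parameter choices

Default parameters make both resident pairs mutualistic and the communities
symmetric: `q_h = 2, q_c = 1` for hosts, `q_c = 2, q_h = 1` for symbionts,
`α_nn = α_ii = β_nn = β_ii = 1`, cross coefficients 0, `d = 1`, `r = 0.5`,
`μ = 1`, `c = 0.5`. These are package defaults chosen for a clearly interior
mutualistic equilibrium (`(p_n*, m_n*) = (0.9, 0.6)`), not published values.

The scenario demonstration sets in `experiments.scenario_params` modify the
defaults minimally:

- `1_symmetric`: competition raised to `c = 1.5 > μ` so that symmetric
  communities exclude one another and initial abundance decides the contest.
- `4_native_resistance`: `α_ni = 0.1, β_in = 1.5` — invasive hosts pay much
  more to native symbionts than they receive (cross edge parasitic for the
  invasive host).
- `6_co_invasion`: the mirror, `α_in = 0.1, β_ni = 1.5` — pathogen-like
  invasive symbionts drain native hosts.
- `low_quality_mutualist`: `α_ni = 1, β_in = β_ii = 0.6` with `c = 1` —
  invasive hosts are genuine but weaker mutualists (`Q_m = 0.2` vs the native
  pair's 1.0) that tap the native symbiont network; the natives are displaced
  and the replacement community settles at total biomass ≈ 0.92 vs the
  resident's 1.5 (Δ ≈ −0.58).

Random draws in property tests and the acceptance script are log-uniform over
[1e-2, 10] for rates and coefficients (spanning flux-limited regimes on both
sides of `d`) with `d` log-uniform in [0.5, 2]; the constrained sampler
(`sweeps.sample_params`) uses the same ranges with rejection until the
requested per-edge regimes hold, holding `d = 1` unless told otherwise.

## What the synthetic conditions do and do not show

All inputs here are generated: parameter draws, grids, and propagules. The
experiments demonstrate the model's *mechanisms* — which regime placements
produce which invasion endpoints under deterministic, well-mixed,
two-community dynamics. They do not emulate demographic or environmental
stochasticity, repeated introductions, spatial structure, or multi-strain
communities, so passing tests say nothing about those aspects of real
invasions; they certify the algebra, the numerics, and the documented
scenario logic.

## Known limitations

- Outcome classification near bifurcation boundaries inherits the grid
  resolution of the sweep; non-converged and limit-cycle cells are labelled
  as such rather than resolved.
- Extinction-pathway times are reported on the solver's natural step grid,
  not refined by event root-finding.
- The propagule-monotonicity property is established for mutualistic
  symmetric communities with exclusion-strength competition; with weak
  competition the same contests end in coexistence and propagule size is
  irrelevant.
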