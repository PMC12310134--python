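# Methods

## Agent model

State: N fish with positions `r_i` (body lengths, BL) and unit headings
`p_i` in free 3D space (no boundaries, no hydrodynamics).  Per time step
`dt` every fish synchronously computes a desired heading from the state at
time t:

1. **Repulsion, top priority.** Neighbors with `d_ij ≤ zr` (distance only,
   no vision filter — a flag `vision_filters_repulsion` can change this)
   give desired direction `−Σ r̂_ij`, normalized.
2. **Alignment + attraction** otherwise: the unit-normalized mean heading of
   alignment-shell neighbors (`zr < d ≤ zl`) plus the unit-normalized mean
   bearing of attraction-shell neighbors (`zl < d ≤ za`), renormalized;
   either term is dropped when its shell is empty.  Both shells are
   restricted to the visual field: a neighbor is visible iff the angle
   between heading and bearing is ≤ α/2 (boundary counts as visible; the
   blind cone of apex angle 360°−α is directly behind the heading).
3. A zero resultant, or no neighbors at all, leaves the heading unchanged.
4. **Noise**: i.i.d. Gaussian(0, σ²) added to each Cartesian component of
   the desired heading, then renormalized (a spherically wrapped Gaussian
   about the desired heading; small-σ angular spread ≈ σ√2).
5. **Turn limit**: the angle between the new (noisy) heading and `p_i(t)` is
   clamped to `θmax·dt` by rotating `p_i(t)` within the plane spanned by the
   two headings.  θmax is a turning **rate** (degrees per time unit); the
   per-step budget scales with dt so trajectories are comparable across step
   sizes.  For an exactly antiparallel desired heading the rotation plane is
   undefined; a deterministic perpendicular axis (cross product with the
   least-aligned coordinate axis) breaks the tie without consuming
   randomness.
6. **Advance**: `r_i ← r_i + U·p_i(t+dt)·dt`, using the *new* heading so
   displacement and heading agree within a step.

Defaults (all configurable): N=100, U=3 BL per time unit, zr=1, zl=2,
za=10, α=270°, θmax=40°/time unit, σ=0.01, dt=0.1, T=500.  Initial
conditions: positions uniform in the unit cube, headings uniform on the
sphere.  Coincident positions raise an error rather than being silently
regularized (probability zero under the continuous dynamics).

Two coincident implementations exist: a vectorized numpy path (the
reference) and numba-compiled kernels used when numba imports; a test
asserts bit-level agreement of a full step between the two.

## Observables and phase labels

`P = |mean p_i|`; `M = |mean of unit (r_i − r_c) × p_i|` about the centroid
`r_c` (degenerate contributions — a fish at the centroid or heading along
its radius — count as zero vectors, keeping M defined on symmetric
configurations); NND mean and population standard deviation.  Steady states
are trailing-window averages (50 time units by default) of samples recorded
every 0.5 time units.  Classification: fragmented if mean NND > 8 BL
(cohesion lost); else schooling if P̄ ≥ 0.65 and M̄ < 0.35; milling if
M̄ ≥ 0.65 and P̄ < 0.35; else swarming.  The 0.65/0.35 cutoffs are a
declared convention (the phases they separate are qualitatively distinct);
they are exposed as keyword arguments.

## Protocols

All Monte-Carlo drivers derive replicate streams as
`base_seed + grid_index·n_replicates + replicate`, making every (grid
point, replicate) pair an independent reproducible stream and whole sweeps
bit-reproducible.  The bifurcation sweep reports per-`zl` ensemble means,
schooling/milling fractions, and the transition estimate `zl*` as the first
grid value where the schooling fraction reaches 0.5 (with a linearly
interpolated crossing alongside).  Hysteresis sweeps hold each `zl` for a
fixed time and hand the final state of one hold to the next (state
continuity is the memory mechanism); each replicate traverses the whole
schedule independently, and backward sweeps restart from their own forward
endpoint states.

## Escape analysis

Milling residence uses threshold M ≥ 0.5 (midway; configurable).  The
escape rate is `κ = 1/mean(T_milling)` over replicates that entered
milling; replicates that never milled are excluded from the mean but
reported as a no-milling fraction.  The Kramers-law fit
`κ = A·r·exp(−r/(3σ²))` is linear least squares in log space
(`log κ − log r` on `r`), which is exactly invertible on noiseless data;
an optional nonlinear refinement (`refine=True`) polishes the estimate and
must agree within the reported residuals.  A non-negative fitted slope
(no decaying component) is an error, not a silent extrapolation.

## Transcritical polarization SDE

`dP = rP(1−P)dt + σdW` integrated by Euler–Maruyama (default dt=0.01) with
reflecting boundaries at 0 and 1 — P is a norm-based order parameter
confined to [0,1], and reflection preserves the transcritical phenomenology
without absorbing probability mass.  The effective potential is
`U(P) = −rP²/2 + rP³/3`, the unique antiderivative (gauge U(0)=0) whose
negative gradient is the drift; it gives `U″ = −r, +r` at P = 0, 1 and
barrier magnitude `|ΔU| = |r|/6`.  The default hysteresis schedule sweeps
r from −1 to 1 in steps of 0.1, holding 10 time units per value and
averaging the trailing fifth of each hold.  Loop area is
`|∫(P_fwd − P_bwd)dr|`: the signed integrand makes Monte-Carlo noise
cancel, whereas an absolute-value integrand would report a spurious
positive area of order sd(P)/√n_replicates even for reversible dynamics.
At σ=0.20 the residual quasi-static lag of this schedule leaves a true
area of ≈0.02 P·r units (measured with 3000 replicates), so 50-replicate
estimates of that number scatter around 0.02–0.03.

Kramers parameter recovery from the SDE itself is tested in the regime
where the law applies: for r < 0 the milling equilibrium P=0 is a genuine
potential well with barrier |r|/6 peaking at P=1, and measured mean escape
times across several |r| recover σ from the exponential slope.  For r > 0
the milling state is *unstable* and escape is drift-dominated
(κ ~ r/log-factors, not a Kramers exponential), so recovery is neither
expected nor asserted there.

## What the ensembles emulate — and a known discrepancy

The Monte-Carlo protocols generate the study conditions themselves (no
external data): random-cube initial conditions, the noise level, grid
schedules, hold times, and replicate counts.  Replicate counts in the test
suite and drivers are scaled down (5–20 per condition rather than
hundreds), with tolerance bands sized to the reduced counts; results state
Monte-Carlo fractions, not densities of real fish data.  The model omits
everything a real school adds: body shape and hydrodynamic coupling,
rotational inertia, heterogeneous individuals, boundaries, and sensory
latency.

A documented limitation: with the default parameters (za=10, σ=0.01) the
milling state is only marginally stable and random initial conditions most
often converge to swarming or schooling, so the structure the end-to-end
checks encode for this slice — a 100% milling plateau through zl = 2.8 and a
schooling transition at zl* ≈ 3.1 — is not reproduced at za=10 — the same pipeline exhibits
the full structure (robust M ≈ 0.97 milling plateau through zl = 3,
schooling beyond ≈3.4) at za ≈ 14.  The geometric origin is the turning
circle: at U=3 and θmax=40°/time unit the minimum turning radius is
U/θmax ≈ 4.3 BL, so a freshly disordered group spreads over
U·π/θmax ≈ 13.5 BL while turning around, which exceeds an attraction range
of 10 BL and lets subgroups escape each other's perception before a mill
can close.  A related symptom: the noise dependence of
milling is inverted at this parameter slice (rotational order at low zl is
*higher* at σ=0.10 than at σ=0.01), so the noise-dependent hysteresis
asymmetry is not reproduced either.  An extensive sensitivity study over
discretization, noise placement, term weighting, and field-of-view
conventions did not remove this mismatch without departing from the stated
parameters; the end-to-end tests that encode the za=10 phase boundaries
therefore fail honestly rather than being recalibrated.
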