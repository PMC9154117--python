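# Methods

## Model

Foragers occupy `n + 1` commitment states: uncommitted `U` (index 0) or
committed to patch `i ∈ {1..n}` (input order everywhere).  Three variants
are compiled to mass-action reaction lists shared verbatim by both
engines:

* **asocial** — discovery `U → i` at `q_i` and abandonment `i → U` at `a`
  (2n reactions);
* **positive-only** — plus recruitment `U + i → 2i` at `r_i = ρ`
  (3n reactions);
* **negative-feedback** — recruitment at `r_i = ρ q_i` plus same-patch
  stop signalling `i + i → U + i` at `z` (4n reactions).  Cross-patch
  inhibition is deliberately never generated; the stop signal is
  self-inhibition by patch mates.

Qualities are any positive reals (only ratios enter the target
`x_i* = q_i / Σ q_j`); the canonical scenarios use values in (0, 1].
Recruitment is *equalised* between the social variants: the
negative-feedback coefficient is `ρ = r / mean(q)` (unweighted arithmetic
mean over patches), so the patch-averaged recruitment rate equals the
positive-only constant `r`.  The equalisation convention is recorded in
all output metadata; a target-weighted mean could be swapped behind the
same interface.

Canonical parameters (all rates in events per abstract model time unit):
`q = (0.75, 0.5, 0.25)` (or `(0.75, 0.5)` for two patches), leak
`a = 1e-3`, average recruitment strength `r = 100` (so social recruitment
is ~100× faster than independent discovery, the biologically documented
regime — violating `r_i ≫ q_i` only logs a warning), stop signal
`z = 3.1`, colony size `S = 200`, ensembles evaluated at `t = 400` (three
patches) or `t = 1000` (two patches).

## Mean-field engine

With `x_U` eliminated by conservation the committed fractions obey
`dx_i/dt = q_i x_U − a x_i + r_i x_U x_i − z x_i²`.  Eliminating `x_U`
keeps the Jacobian (`J = −(q + r∘x)·1ᵀ + diag(−a + r x_U − 2 z x)`) free
of the trivial zero mode.  The canonical systems are stiff — `a = 1e-3`
against social rates ~1e2 — so integration uses scipy's implicit BDF with
the analytic Jacobian and defaults `rtol = 1e-10`, `atol = 1e-12`
(needed for the five-orders-of-magnitude delay measurement to be
tolerance-robust; LSODA was tried first and stalled on some post-switch
trajectories when its method switching met these tolerances).  Simplex
violations beyond 1e-9 trigger one automatic retry at 100× tighter
tolerances and are otherwise an error — states are never clipped.

Fixed points: the positive-only variant has the closed form
`x_i = q_i u / (a − ρ u)` with `u` the smaller root of
`ρ u² − (ρ + a + Q) u + a = 0` (`Q = Σ q_j`), evaluated in its
cancellation-free form; the asocial variant has `x_i = q_i x_U / a`,
`x_U = a/(a + Q)`.  Everything else is Newton-polished root finding
(scipy `hybr` plus explicit Newton iterations) started from the
quality-proportional interior state, falling back to long-time
integration; the returned residual satisfies `max |dx/dt| < 1e-12`, and
only interior, linearly stable points are reported (boundary landings are
logged and raised).  Stability is judged from the analytic Jacobian
spectrum, never finite differences.

Convergence time is the first *sustained* entry into the ball
`Σ_i (x_i − ref_i)² < tol` (default `tol = 1e-4`): the last downward
tolerance crossing detected by the integrator's event machinery before
the horizon (default 1e10), so tangential grazing does not count.  The
caller chooses the reference: the Eq-target for the positive-only and
asocial variants (whose fixed points satisfy the tolerance), the
system's own fixed point for negative-feedback sweeps, where the
steady-state offset can exceed `tol`.

Default initial condition is the fully uncommitted colony; the canonical
perturbed condition is `x₁ = x₂ = 0, x₃ = 0.05`.  The symmetric choice
matters: from the uncommitted state the positive-only dynamics stay
exactly on the quality-proportional manifold, which is why they look
fast — any asymmetric perturbation excites the slow mode
(`−a + ρ x_U* ≈ −1.5e-5` at canonical rates) and delays convergence by
more than five orders of magnitude.

## Exactness point and normalisation convention

Substituting `x_i = c q_i`, `x_U = a c` into the negative-feedback rate
equations zeroes every component iff `z = a ρ`; conservation then gives
`c = 1/(a + Q)`.  The fixed point at this `z` is therefore *exactly*
quality-proportional, but its committed total is `Q/(a + Q) < 1`, so its
raw squared distance from the sum-to-one target is `(a c / Q)² Σ q_i²`
(~1.7e-7 at canonical rates), not zero.  The package consequently keeps
two distances:

* `metrics.r2_error` — raw `Σ (x_i − x_i*)²` over committed fractions,
  the definition used for the SSE distributions and the trade-off error
  curve;
* `metrics.allocation_r2` — the same distance after normalising the
  committed allocation (`x/Σx`), which is exactly zero at `z = a ρ` and
  is the objective of the stop-signal optimiser and of all "hits the
  target exactly" checks.

## Stop-signal parameterisation

`exact_z(a, ρ) = a ρ` is the closed-form exactness point.
`optimise_z(min_error)` minimises the allocation error over `z` with a
deterministic log-grid plus golden-section refinement (no stochastic
optimisation, hence no seeds) and recovers `a ρ` to well under 1%; it
serves as a built-in self-test.  `optimise_z(error_speed_tradeoff, λ)`
minimises `allocation R² + λ · convergence time` (time to the system's
own fixed point), exposing the speed–robustness dial.  The canonical
`z = 3.1` (= 15.5 `a ρ`) is treated as a given scenario parameter — it
exceeds the exactness point, trading a ~6.5e-5 steady-state error for
convergence in a few time units; the weighting that would produce it is
not claimed.

The rate-function search parameterises every (recruitment family ∈
{constant, linear-in-quality}) × (stop signalling on/off) combination at
equalised average strength, tuning `z` by `min_error` where present, and
ranks by fixed-point allocation error.  It shows that without negative
feedback constant recruitment reaches the target exactly, while with
stop signalling the recruitment must become linear in quality: the
positive-only fixed point is only marginally stable (slow mode
`≈ −1.5e-5`), so even a tiny constant-recruitment stop signal displaces
the allocation O(1).

In the trade-off ("fig3") sweeps, the `z` grid varies at fixed canonical
`ρ`, with convergence measured to each system's fixed point (time falls,
error rises).  The `ρ` sweep holds the *relative* inhibition `z/(a ρ)`
at its canonical value — the stop-signal strength tracks the recruitment
scale, as under the quality-based rate heuristic — whereupon both time
and error fall monotonically; at fixed absolute `z` the convergence time
instead rises slowly with `ρ` (measured: 7.0 → 10.4 over `ρ` 200 → 3200).

## Stochastic engine

Gillespie's direct method, exact by construction: two uniforms per event
(exponential waiting time from the total propensity; channel proportional
to propensity), integer counts conserved at every event.  Microscopic
convention: bimolecular propensities divide by `S` (not `S − 1`) and
same-species stop signalling uses the ordered-pair count `X_i (X_i − 1)`
without a ½ symmetry factor, so `(1/S)·propensity` reproduces the
mean-field terms `r_i x_U x_i` and `z x_i²` exactly as written — the two
engines are mutually consistent by construction, which is the testable
contract (absolute `z`-dependent quantities could differ by an O(1)
factor from other microscopic conventions; all orderings and
mean-field-agreement checks are robust to this).  The inner loop is a
numba kernel; no tau-leaping or other approximate accelerations exist.

Runs record left-hold (right-continuous) samples on a fixed 401-point
grid over `[0, t_end]`; full event logs are optional and meant for
small-scale invariant checking.  Per-run seeds derive from the master
seed as `SeedSequence(master_seed, spawn_key=(run_index,))` and are
recorded in outputs; ensembles are bit-for-bit reproducible, and variant
comparisons reuse the same derived seed stream (paired seeds) so variance
orderings are not confounded by sampling luck.

## Experiments and scale

The composed experiments are pure functions of `(config, seed)`; outputs
are tidy CSVs, a JSON summary, and a manifest with SHA-256 checksums.
Ensembles default to 200 runs (100 in the sweeps), at which scale the
variance and SSE orderings are resolved with large margins (the per-patch
variance ratio between variants is ~45×); boxplot statistics use the
conventional Tukey definition and are exported per patch and pooled,
since either presentation may be wanted.  Deviation-tail probabilities
come with Wilson 95% binomial intervals, with the threshold defaulting to
the negative-feedback ensemble's 95th percentile (a reconstruction
choice, recorded in the summary).  The adaptation report operationalises
"state-independent responsiveness" as the coefficient of variation of
re-convergence times across random initial allocations — a package
definition, labelled as such in the outputs.

The asocial baseline reports both its slowest-eigenvalue timescale
(`1/a`, the leak) and symmetric-start convergence times.  Note one
asymmetry: the positive-only variant's *slowest eigenvalue* is even
slower than the asocial leak, yet its symmetric-start convergence is
fast because the symmetric start never excites that mode; comparisons in
the report therefore pair the asocial eigen-timescale with the social
variants' symmetric convergence times, and eigen-timescales only between
asocial and negative-feedback.

## What the simulations do and do not show

The generators emulate exactly the model's idealised conditions:
well-mixed populations, constant patch qualities within a run,
memoryless individuals, and mass-action encounter rates.  Passing tests
therefore demonstrate internal consistency of the two engines and the
claimed orderings *within this model class*; they say nothing about
spatial structure, time-correlated interactions, quality estimation
noise, or real forager physiology.  The stationary ensemble mean of the
negative-feedback model sits slightly below the target on the best patch
(the fixed-point offset at `z = 3.1` plus an O(1/S) master-equation
correction, together ≈ 0.009 at `S = 200`) — a real property of the
model, resolvable at a few hundred runs, and invisible at boxplot
resolution.

## Known limitations

No spatial or network-structured populations, no delay dynamics, no
bifurcation continuation beyond the `z`/`ρ` grids, no time-varying
qualities within a single SSA segment (environmental switches are
composed by chaining runs), and no general CRN DSL — only the three
variants plus the rate-function families above.
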