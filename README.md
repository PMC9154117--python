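# foragesim

Reaction-network models of collective foraging regulation in social-insect
colonies, with a deterministic mean-field engine and an exact stochastic
engine.

## The problem

A colony of `S` foragers must allocate itself over `n` forage patches with
qualities `q_i` so that the fraction committed to patch `i` approaches the
quality-proportional target

    x_i* = q_i / Σ_j q_j .

Each forager is either uncommitted (`U`) or committed to one patch, and
changes state through four mass-action reaction classes:

| transition | reaction | rate |
|---|---|---|
| independent discovery | `U → i` | `q_i` |
| abandonment (leak) | `i → U` | `a` |
| recruitment (positive social feedback) | `U + i → 2i` | `r_i` |
| stop signalling (negative social feedback, self-inhibition) | `i + i → U + i` | `z` |

Two social variants are compared at equalised average recruitment strength
`r`: **positive-only** (`r_i = ρ`, `z = 0`) and **negative-feedback**
(`r_i = ρ q_i`, `z > 0`), plus an **asocial** baseline with discovery and
abandonment only.  In the infinite-population limit both social variants
converge to (near) the target, but in finite colonies they differ sharply:
demographic noise lets the positive-only colony freeze far from the
target, while stop signalling continually re-randomises commitment and
suppresses the stationary variance — at the price of a steady-state offset
that grows with `z` (a tunable speed–robustness trade-off).

The mean-field dynamics in committed fractions (with `x_U = 1 − Σ_j x_j`) are

    dx_i/dt = q_i x_U − a x_i + r_i x_U x_i − z x_i² ,

integrated with a stiff implicit method (BDF, analytic Jacobian); finite
populations are simulated exactly with Gillespie's direct method on the
same compiled reaction systems.

## Worked example

```python
import numpy as np
import foragesim as fs
from foragesim import mean_field as mf, stochastic as st, metrics

env = fs.make_environment([0.75, 0.5, 0.25])
target = fs.target_distribution(env)
print("target:", np.round(target.values, 4))

neg = fs.build_system("negative_feedback", env, a=1e-3, r=100.0, z=3.1)
pos = fs.build_system("positive_only", env, a=1e-3, r=100.0)

report = mf.find_fixed_point(neg)
print("negative-feedback fixed point:", np.round(report.fixed_point.x, 4),
      "stable:", report.stable)

for name, system in [("positive-only", pos), ("negative-feedback", neg)]:
    ens = st.run_ensemble(system, S=200, n_runs=200, t_end=400.0, master_seed=0)
    var = metrics.ensemble_variance(ens, 400.0)
    print(f"{name:17s} variance at t=400:", np.round(var, 5))

t_sym = mf.convergence_time(pos, None, target)
t_pert = mf.convergence_time(pos, mf.MeanFieldState(np.array([0., 0., 0.05])), target)
print(f"perturbation delay: {metrics.delay_log10(t_pert, t_sym):.2f} orders of magnitude")
```

prints

```
target: [0.5    0.3333 0.1667]
negative-feedback fixed point: [0.4927 0.33   0.1672] stable: True
positive-only     variance at t=400: [0.06385 0.05902 0.02877]
negative-feedback variance at t=400: [0.00143 0.00138 0.00067]
perturbation delay: 6.56 orders of magnitude
```

Reading the numbers: the negative-feedback fixed point sits close to (but
deliberately not exactly at) the target — the small offset is the price of
a stop signal strong enough to converge in a few time units.  Across 200
stochastic runs of a 200-forager colony the per-patch variance of the
committed fractions is ~45× smaller with stop signalling.  And the
positive-only mean-field dynamics, started with just 5% of the colony
mis-committed to the worst patch, take more than six orders of magnitude
longer to reach the target than from the symmetric uncommitted start.

## Command line

```
forage simulate ode --config model.yaml --t-end 400 --out traj.csv
forage simulate ssa --config model.yaml -S 200 --runs 30 --seed 1 --out runs.csv
forage experiment fig1 --seed 1 --outdir out/        # also fig2, fig3, sweep,
                                                     # adaptation, asocial, deviation
forage parameterise --config model.yaml --objective min_error
forage rate-functions --config model.yaml
```

Model configs are YAML mappings (`variant`, `qualities`, `a`, `r`, `z`,
optional `ρ`); experiments write tidy CSV tables, a JSON summary, and a
checksummed manifest so every output is reproducible from
`(config, seed)`.

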