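"""Composed experiments: the canonical scenarios and parameter sweeps.

Every experiment is a pure function of its configuration and a master
seed: re-running with the same inputs reproduces every output byte.
Variant comparisons are paired by seed — both variants consume the same
derived per-run seed stream — so orderings of ensemble variance are not
confounded by sampling luck.  Outputs are tidy CSV tables plus a JSON
summary and a checksummed manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import mean_field, metrics, presets, stochastic
from .mean_field import MeanFieldState, fully_uncommitted
from .model_core import make_environment, system_to_config, target_distribution
from .parameterisation import build_system

__all__ = [
    "fig1",
    "fig2",
    "fig3",
    "sweep",
    "adaptation",
    "asocial_baseline",
    "deviation_probability",
    "write_outputs",
]


def _social_systems(cfg: dict):
    env = make_environment(cfg["qualities"])
    pos = build_system("positive_only", env, a=cfg["a"], r=cfg["r"])
    neg = build_system("negative_feedback", env, a=cfg["a"], r=cfg["r"], z=cfg["z"])
    return env, pos, neg


def _ode_table(systems: dict, t_end: float) -> pd.DataFrame:
    t_eval = np.linspace(0.0, t_end, stochastic.DEFAULT_GRID_POINTS)
    frames = []
    for name, system in systems.items():
        traj = mean_field.integrate(system, t_end=t_end, t_eval=t_eval)
        frame = traj.to_frame()
        frame.insert(0, "variant", name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def fig1(seed: int, config: "dict | None" = None, outdir: "str | None" = None) -> dict:
    """Trajectories, ensemble statistics at t=400, and the perturbation delay.

    Compares both social variants in the canonical three-patch scenario:
    ODE trajectories, paired SSA ensembles with per-patch variance and
    Tukey boxplot statistics at the evaluation time, and the
    positive-only model's convergence times from the symmetric
    (fully-uncommitted) versus slightly perturbed initial conditions.
    """
    cfg = presets.merged(presets.FIG1, config)
    env, pos, neg = _social_systems(cfg)
    target = target_distribution(env)
    systems = {"positive_only": pos, "negative_feedback": neg}

    ode = _ode_table(systems, cfg["t_end"])

    ens = {
        name: stochastic.run_ensemble(
            system, cfg["S"], cfg["n_runs"], cfg["t_end"], master_seed=seed
        )
        for name, system in systems.items()
    }
    t_eval = cfg["eval_time"]
    stats_rows, box_rows = [], []
    for name, e in ens.items():
        fr = e.committed_fractions_at(t_eval)
        var = metrics.ensemble_variance(e, t_eval)
        for i in range(env.n):
            stats_rows.append(
                {
                    "variant": name,
                    "patch": i + 1,
                    "time": t_eval,
                    "mean": fr[:, i].mean(),
                    "variance": var[i],
                    "stderr": fr[:, i].std(ddof=1) / np.sqrt(cfg["n_runs"]),
                    "target": target.values[i],
                }
            )
            box_rows.append({"variant": name, "patch": str(i + 1),
                             **metrics.tukey_summary(fr[:, i])})
        box_rows.append({"variant": name, "patch": "pooled",
                         **metrics.tukey_summary(fr.ravel())})

    tol = cfg["convergence_tol"]
    t_sym = mean_field.convergence_time(pos, None, target, tol=tol)
    t_pert = mean_field.convergence_time(
        pos, MeanFieldState(np.asarray(cfg["perturbed_init"])), target, tol=tol
    )
    perturbation = {
        "t_symmetric": t_sym,
        "t_perturbed": t_pert,
        "delay_log10": metrics.delay_log10(t_pert, t_sym),
        "tolerance": tol,
    }

    result = {
        "config": cfg,
        "tables": {
            "ode_trajectories": ode,
            "ensemble_stats": pd.DataFrame(stats_rows),
            "boxplots": pd.DataFrame([
                {k: (json.dumps(v) if isinstance(v, list) else v)
                 for k, v in row.items()} for row in box_rows
            ]),
            "ssa_trajectories": pd.concat(
                [e.to_frame().assign(variant=name) for name, e in ens.items()],
                ignore_index=True,
            ),
        },
        "summary": {
            "experiment": "fig1",
            "target": target.values.tolist(),
            "perturbation": perturbation,
            "ensembles": {name: e.summary([t_eval]) for name, e in ens.items()},
        },
    }
    if outdir:
        write_outputs(outdir, "fig1", result)
    return result


def fig2(seed: int, config: "dict | None" = None, outdir: "str | None" = None) -> dict:
    """Per-run sum of squared errors at convergence for both variants."""
    cfg = presets.merged(presets.FIG2, config)
    env, pos, neg = _social_systems(cfg)
    target = target_distribution(env)
    rows, summaries = [], {}
    for name, system in (("positive_only", pos), ("negative_feedback", neg)):
        e = stochastic.run_ensemble(
            system, cfg["S"], cfg["n_runs"], cfg["t_end"], master_seed=seed
        )
        values = metrics.sse(e, target, cfg["eval_time"])
        rows += [{"variant": name, "run_id": i, "sse": v}
                 for i, v in enumerate(values)]
        summaries[name] = metrics.tukey_summary(values)
    result = {
        "config": cfg,
        "tables": {"sse": pd.DataFrame(rows)},
        "summary": {
            "experiment": "fig2",
            "target": target.values.tolist(),
            "tukey": summaries,
            "median_ratio": summaries["positive_only"]["median"]
            / summaries["negative_feedback"]["median"],
        },
    }
    if outdir:
        write_outputs(outdir, "fig2", result)
    return result


def fig3(seed: int = 0, config: "dict | None" = None, outdir: "str | None" = None) -> dict:
    """Speed–robustness trade-off curves from the infinite-population model.

    Along an increasing stop-signal grid the convergence time (to the
    system's own stable fixed point, error threshold 1e-4) falls while the
    fixed point's squared distance from the quality-proportional target
    rises; along an increasing recruitment-coefficient grid both fall.
    """
    cfg = presets.merged(presets.FIG3, config)
    env = make_environment(cfg["qualities"])
    target = target_distribution(env)
    tol = cfg["convergence_tol"]

    def point(rho: float, z: float) -> dict:
        system = build_system("negative_feedback", env, a=cfg["a"],
                              r=rho * env.qualities.mean(), z=z, rho=rho)
        report = mean_field.find_fixed_point(system)
        r2 = metrics.r2_error(report.fixed_point.x, target)
        try:
            t_conv = mean_field.convergence_time(
                system, None, report.fixed_point.x, tol=tol,
                check_fixed_point=False,
            )
        except mean_field.ConvergenceError:
            t_conv = np.nan  # reported, not silently dropped
        return {"rho": rho, "z": z, "fixed_point_r2": r2,
                "convergence_time": t_conv, "stable": report.stable}

    rho_canon = cfg["r"] / env.qualities.mean()
    z_rows = [point(rho_canon, z) for z in cfg["z_grid"]]
    # the rho sweep holds the *relative* inhibition z/(a*rho) at its
    # canonical value: the stop-signal strength tracks the recruitment
    # scale, as under the quality-based rate heuristic
    z_rel = cfg["z"] / (cfg["a"] * rho_canon)
    rho_rows = [point(rho, z_rel * cfg["a"] * rho) for rho in cfg["rho_grid"]]
    z_tab, rho_tab = pd.DataFrame(z_rows), pd.DataFrame(rho_rows)
    result = {
        "config": cfg,
        "tables": {"z_sweep": z_tab, "rho_sweep": rho_tab},
        "summary": {
            "experiment": "fig3",
            "z_time_strictly_decreasing":
                bool(np.all(np.diff(z_tab["convergence_time"]) < 0)),
            "z_error_strictly_increasing":
                bool(np.all(np.diff(z_tab["fixed_point_r2"]) > 0)),
            "rho_time_decreasing":
                bool(np.all(np.diff(rho_tab["convergence_time"]) < 0)),
            "rho_error_decreasing":
                bool(np.all(np.diff(rho_tab["fixed_point_r2"]) < 0)),
        },
    }
    if outdir:
        write_outputs(outdir, "fig3", result)
    return result


def sweep(seed: int, config: "dict | None" = None, outdir: "str | None" = None) -> dict:
    """Variance-reduction grid over (S, r, qualities) with paired seeds.

    With ``a_values`` set, runs the abandonment sub-sweep instead: the
    positive-only model's leak rate is varied across the grid while the
    negative-feedback model stays at its canonical rates, asking whether
    extra asocial negative feedback (abandonment) alone can match the
    variance suppression of stop signalling.
    """
    cfg = presets.merged(presets.SWEEP, config)
    rows = []
    t_eval = cfg["eval_time"]
    if cfg.get("a_values"):
        qualities = cfg["quality_sets"][0]
        env = make_environment(qualities)
        S, r = cfg["S_values"][0], cfg["r_values"][0]
        neg = build_system("negative_feedback", env, a=cfg["a"], r=r, z=cfg["z"])
        e_neg = stochastic.run_ensemble(neg, S, cfg["n_runs"], cfg["t_end"], seed)
        var_neg = metrics.ensemble_variance(e_neg, t_eval)
        for a_pos in cfg["a_values"]:
            pos = build_system("positive_only", env, a=a_pos, r=r)
            e_pos = stochastic.run_ensemble(pos, S, cfg["n_runs"], cfg["t_end"], seed)
            var_pos = metrics.ensemble_variance(e_pos, t_eval)
            for i in range(env.n):
                rows.append(
                    {"a_positive_only": a_pos, "S": S, "r": r, "patch": i + 1,
                     "var_positive_only": var_pos[i],
                     "var_negative_feedback": var_neg[i],
                     "variance_ratio": var_neg[i] / var_pos[i]}
                )
        table = pd.DataFrame(rows)
        summary = {
            "experiment": "abandonment_sweep",
            "fraction_ratio_below_1":
                float((table["variance_ratio"] < 1.0).mean()),
            "positive_only_ever_below_negative":
                bool((table["var_positive_only"] < table["var_negative_feedback"]).any()),
        }
    else:
        for qualities in cfg["quality_sets"]:
            env = make_environment(qualities)
            for S in cfg["S_values"]:
                for r in cfg["r_values"]:
                    pos = build_system("positive_only", env, a=cfg["a"], r=r)
                    neg = build_system("negative_feedback", env, a=cfg["a"],
                                       r=r, z=cfg["z"])
                    e_pos = stochastic.run_ensemble(pos, S, cfg["n_runs"],
                                                    cfg["t_end"], seed)
                    e_neg = stochastic.run_ensemble(neg, S, cfg["n_runs"],
                                                    cfg["t_end"], seed)
                    var_pos = metrics.ensemble_variance(e_pos, t_eval)
                    var_neg = metrics.ensemble_variance(e_neg, t_eval)
                    for i in range(env.n):
                        rows.append(
                            {"qualities": json.dumps(list(qualities)), "S": S,
                             "r": r, "patch": i + 1,
                             "var_positive_only": var_pos[i],
                             "var_negative_feedback": var_neg[i],
                             "variance_ratio": var_neg[i] / var_pos[i]}
                        )
        table = pd.DataFrame(rows)
        summary = {
            "experiment": "sweep",
            "fraction_ratio_below_1": float((table["variance_ratio"] < 1.0).mean()),
            "all_points_reduced": bool((table["variance_ratio"] < 1.0).all()),
        }
    result = {"config": cfg, "tables": {"sweep": table}, "summary": summary}
    if outdir:
        write_outputs(outdir, "sweep", result)
    return result


def adaptation(seed: int, config: "dict | None" = None,
               outdir: "str | None" = None) -> dict:
    """Re-convergence after an environmental switch, across initial states.

    Integrates each variant from random initial allocations to the switch
    time, swaps the patch qualities, and measures the time to re-converge
    to the new fixed point.  The spread (coefficient of variation) of
    these times across initial states quantifies how state-dependent each
    variant's responsiveness is.
    """
    cfg = presets.merged(presets.ADAPTATION, config)
    env_before = make_environment(cfg["qualities_before"])
    env_after = make_environment(cfg["qualities_after"])
    tol = cfg["convergence_tol"]
    rng = np.random.default_rng(seed)
    inits = rng.dirichlet(np.ones(env_before.n + 1), size=cfg["n_inits"])[:, 1:]
    rows = []
    for variant, z in (("positive_only", 0.0), ("negative_feedback", cfg["z"])):
        before = build_system(variant, env_before, a=cfg["a"], r=cfg["r"], z=z)
        after = build_system(variant, env_after, a=cfg["a"], r=cfg["r"], z=z)
        fp_after = mean_field.find_fixed_point(after).fixed_point
        for k, x0 in enumerate(inits):
            traj = mean_field.integrate(
                before, MeanFieldState(x0), t_end=cfg["switch_time"],
                t_eval=np.array([cfg["switch_time"]]),
            )
            t_re = mean_field.convergence_time(
                after, traj.final_state, fp_after.x, tol=tol,
                check_fixed_point=False,
            )
            rows.append({"variant": variant, "init_id": k,
                         "reconvergence_time": t_re})
    table = pd.DataFrame(rows)
    cv = {}
    for variant, grp in table.groupby("variant"):
        t = grp["reconvergence_time"].to_numpy()
        cv[variant] = float(t.std(ddof=1) / t.mean())
    result = {
        "config": cfg,
        "tables": {"adaptation": table},
        "summary": {
            "experiment": "adaptation",
            "cv": cv,
            "cv_ratio_pos_over_neg":
                cv["positive_only"] / cv["negative_feedback"],
        },
    }
    if outdir:
        write_outputs(outdir, "adaptation", result)
    return result


def asocial_baseline(seed: int, config: "dict | None" = None,
                     outdir: "str | None" = None) -> dict:
    """Discovery-and-abandonment-only baseline next to the social variants.

    The asocial fixed point is exactly quality-proportional
    (x_i = q_i x_U / a, x_U = a/(a+Q)), but its slowest relaxation
    eigenvalue is the leak -a, so reallocation is orders of magnitude
    slower than with social feedback.
    """
    cfg = presets.merged(presets.ASOCIAL, config)
    env = make_environment(cfg["qualities"])
    target = target_distribution(env)
    rows = []
    variants = {
        "asocial": build_system("asocial", env, a=cfg["a"], r=cfg["r"]),
        "positive_only": build_system("positive_only", env, a=cfg["a"], r=cfg["r"]),
        "negative_feedback": build_system("negative_feedback", env, a=cfg["a"],
                                          r=cfg["r"], z=cfg["z"]),
    }
    for name, system in variants.items():
        report = mean_field.find_fixed_point(system)
        t_conv = mean_field.convergence_time(
            system, None, report.fixed_point.x, tol=cfg["convergence_tol"],
            check_fixed_point=False,
        )
        e = stochastic.run_ensemble(system, cfg["S"], cfg["n_runs"],
                                    cfg["t_end"], seed)
        var = metrics.ensemble_variance(e, cfg["eval_time"])
        rows.append(
            {
                "variant": name,
                "fixed_point": json.dumps(report.fixed_point.x.tolist()),
                "fixed_point_r2_to_target":
                    metrics.r2_error(report.fixed_point.x, target),
                "slowest_eigenvalue": float(np.max(report.eigenvalues.real)),
                "eigen_timescale": float(1.0 / abs(np.max(report.eigenvalues.real))),
                "convergence_time_symmetric": t_conv,
                "mean_ssa_variance": float(var.mean()),
            }
        )
    table = pd.DataFrame(rows)
    by = table.set_index("variant")
    result = {
        "config": cfg,
        "tables": {"asocial_baseline": table},
        "summary": {
            "experiment": "asocial_baseline",
            "asocial_vs_negative_eigen_timescale_ratio":
                float(by.loc["asocial", "eigen_timescale"]
                      / by.loc["negative_feedback", "eigen_timescale"]),
            "asocial_eigen_timescale_vs_social_convergence": {
                name: float(by.loc["asocial", "eigen_timescale"]
                            / by.loc[name, "convergence_time_symmetric"])
                for name in ("positive_only", "negative_feedback")
            },
        },
    }
    if outdir:
        write_outputs(outdir, "asocial", result)
    return result


def deviation_probability(seed: int, config: "dict | None" = None,
                          outdir: "str | None" = None) -> dict:
    """Probability of a large deviation from the target at the eval time.

    Reports, per variant, the empirical probability that a run's squared
    distance from the target exceeds a threshold delta, with Wilson 95%
    binomial confidence intervals.  By default delta is set to the
    negative-feedback ensemble's 95th percentile (a reconstruction choice,
    recorded in the summary).
    """
    from scipy.stats import binomtest

    cfg = presets.merged(presets.DEVIATION, config)
    env, pos, neg = _social_systems(cfg)
    target = target_distribution(env)
    values = {}
    for name, system in (("positive_only", pos), ("negative_feedback", neg)):
        e = stochastic.run_ensemble(system, cfg["S"], cfg["n_runs"],
                                    cfg["t_end"], seed)
        values[name] = metrics.sse(e, target, cfg["eval_time"])
    delta = cfg.get("delta")
    delta_provenance = "caller-supplied"
    if delta is None:
        delta = float(np.quantile(values["negative_feedback"], 0.95))
        delta_provenance = "95th percentile of negative-feedback R^2 (default)"
    rows = []
    for name, v in values.items():
        k, n = int((v > delta).sum()), v.size
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
        rows.append({"variant": name, "delta": delta, "n_runs": n,
                     "n_exceed": k, "probability": k / n,
                     "ci_low": float(ci.low), "ci_high": float(ci.high)})
    table = pd.DataFrame(rows)
    result = {
        "config": cfg,
        "tables": {"deviation_probability": table},
        "summary": {
            "experiment": "deviation_probability",
            "delta": delta,
            "delta_provenance": delta_provenance,
            "probabilities": {r["variant"]: r["probability"] for r in rows},
        },
    }
    if outdir:
        write_outputs(outdir, "deviation", result)
    return result


def write_outputs(outdir: "str | Path", name: str, result: dict) -> Path:
    """Write tables as CSV plus a JSON summary and a checksummed manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for tab_name, frame in result["tables"].items():
        path = out / f"{name}_{tab_name}.csv"
        frame.to_csv(path, index=False)
        files.append(path)
    summary_path = out / f"{name}_summary.json"
    summary_path.write_text(json.dumps(result["summary"], indent=2, default=float))
    files.append(summary_path)
    config_blob = json.dumps(result["config"], sort_keys=True, default=float)
    manifest = {
        "experiment": name,
        "config": result["config"],
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest(),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files
        },
    }
    manifest_path = out / f"{name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    return manifest_path
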