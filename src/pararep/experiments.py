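"""Parameter sweeps, replicate management and run configuration files.

The sweep harness runs the standard experimental designs (grids
over population size, replicability distance, mutation rate, inflow rate,
duplex decay factor) at full or reduced scale.  Seed policy: a master seed
feeds ``numpy.random.SeedSequence``, which yields one 31-bit seed per
replicate; the same per-replicate seed list is shared across all grid cells
so that cell contrasts are paired.  Seed lists are stored in the tidy
output for exact replay.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import yaml

from .chemostat import ChemostatConfig, run_chemostat
from .constant_population import ConstantPopulationConfig, run_constant
from .kinetics import KineticParams
from .observables import SURVIVAL_CUTOFF, assess_survival, rank_sum_stats

log = logging.getLogger("pararep")


def replicate_seeds(master_seed: int, replicates: int) -> list[int]:
    """Per-replicate 31-bit seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s % (2**31)) for s in ss.generate_state(replicates)]


def scale_down(config, factor: float):
    """Reduced-scale copy of a run configuration.

    Divides the replication-event cap and the survival cadence/window by
    *factor*, preserving the 5:1 window:cadence structure (six samples);
    kinetic parameters are untouched.  Scaling that would leave fewer than
    six window samples is an error.
    """
    if factor < 1:
        raise ValueError("scale factor must be >= 1")
    cadence = round(config.survival_cadence / factor)
    if cadence < 1:
        raise ValueError(
            f"factor {factor} reduces the survival window below 6 samples")
    window = 5 * cadence
    events = max(window, round(config.max_repl_events / factor))
    events = ((events + cadence - 1) // cadence) * cadence
    return replace(config, max_repl_events=events,
                   survival_cadence=cadence, survival_window=window)


def set_param(config, name: str, value):
    """Return a config copy with *name* set, looking the field up on the
    config itself first and on its kinetics block second."""
    if name in {f.name for f in dataclasses.fields(config)}:
        return replace(config, **{name: value})
    if name in {f.name for f in dataclasses.fields(config.kinetics)}:
        return replace(config, kinetics=replace(config.kinetics,
                                                **{name: value}))
    raise ValueError(f"unknown parameter {name!r}")


def _runner_for(config):
    if isinstance(config, ConstantPopulationConfig):
        return run_constant
    if isinstance(config, ChemostatConfig):
        return run_chemostat
    raise TypeError(f"unsupported config type {type(config)!r}")


def sweep(base_config, grid: dict[str, list], replicates: int,
          master_seed: int, cutoff: float = SURVIVAL_CUTOFF,
          out_dir=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a full factorial sweep and aggregate the survival statistics.

    Returns ``(runs, aggregate)``: one tidy row per (cell, replicate) and
    one aggregate row per cell (mean/SD of survivor counts and percentages,
    mean population size, simplex-duplex asymmetry, rank-sum statistics).
    Replicate failures are recorded and flagged; aggregation continues.
    """
    runner = _runner_for(base_config)
    seeds = replicate_seeds(master_seed, replicates)
    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[n] for n in names)):
        config = base_config
        for n, v in zip(names, values):
            config = set_param(config, n, v)
        cell = dict(zip(names, values))
        for rep, seed in enumerate(seeds):
            row = dict(cell, replicate=rep, seed=seed)
            try:
                traj = runner(config, seed=seed)
                surv = assess_survival(traj, cutoff=cutoff)
                rho, rho_max, rho_rand = rank_sum_stats(surv, traj.T)
                n_win = traj.params["survival_window"] // \
                    traj.params["survival_cadence"] + 1
                freq_sum = float(np.nansum(
                    traj.frequencies().iloc[-n_win:].to_numpy(), axis=1
                ).mean())
                gc = traj.master_set.gc_contents()
                row.update(
                    n_survivors=len(surv),
                    pct_survivors=100.0 * len(surv) / traj.T,
                    rho=rho, rho_max=rho_max, rho_rand=rho_rand,
                    mean_N=float(traj.samples["N"].mean()),
                    chi_final=traj.final_chi(),
                    master_freq_sum=freq_sum,
                    gc_survived=float(gc[sorted(surv)].mean())
                    if surv else float("nan"),
                    gc_extinct=float(gc[[i for i in range(traj.T)
                                         if i not in surv]].mean())
                    if len(surv) < traj.T else float("nan"),
                    survivors=";".join(str(i + 1) for i in sorted(surv)),
                    failed=False,
                )
            except Exception as exc:  # noqa: BLE001 - aggregation continues
                log.warning("replicate failed (%s, seed %s): %s",
                            cell, seed, exc)
                row.update(failed=True, error=str(exc))
            rows.append(row)
            log.info("sweep cell %s replicate %d done", cell, rep)
    runs = pd.DataFrame(rows)
    ok = runs[~runs["failed"]]
    agg = (ok.groupby(names, sort=False)
             .agg(n_runs=("n_survivors", "size"),
                  mean_survivors=("n_survivors", "mean"),
                  sd_survivors=("n_survivors", "std"),
                  mean_pct=("pct_survivors", "mean"),
                  sd_pct=("pct_survivors", "std"),
                  mean_N=("mean_N", "mean"),
                  mean_chi=("chi_final", "mean"),
                  mean_rho=("rho", "mean"))
             .reset_index())
    agg["any_failed"] = (runs.groupby(names, sort=False)["failed"].any()
                             .reset_index(drop=True))
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        runs.to_csv(out / "runs.csv", index=False)
        agg.to_csv(out / "aggregate.csv", index=False)
    return runs, agg


# ---------------------------------------------------------------------------
# run-configuration files (YAML, keys mirroring the model parameter names)

_KINETIC_KEYS = {f.name for f in dataclasses.fields(KineticParams)}


def save_config(config, path) -> None:
    data = dataclasses.asdict(config)
    kin = data.pop("kinetics")
    data.update(kin)
    data["model"] = ("constant"
                     if isinstance(config, ConstantPopulationConfig)
                     else "chemostat")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    model = data.pop("model", "constant")
    kin = KineticParams(**{k: v for k, v in data.items()
                           if k in _KINETIC_KEYS})
    rest = {k: v for k, v in data.items() if k not in _KINETIC_KEYS}
    cls = ConstantPopulationConfig if model == "constant" else ChemostatConfig
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(rest) - field_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(kinetics=kin, **rest)


# ---------------------------------------------------------------------------
# desk-scale variants of the full experimental designs
#
# The full designs run 10^7 replication events per trajectory (2*10^6
# for the balanced-GC design); the reductions below divide events and the
# survival window by the stated scale factors so a full design completes in
# minutes on one core, preserving the 5:1 window:cadence structure and the
# full designs' replicate counts where affordable.

#: default reduction for the constant-population designs (10^7 -> 2*10^4)
DESK_SCALE = 500


def coexistence_grid(n_values=(300, 1000), delta_values=(0.001, 0.01),
                     replicates: int = 20, master_seed: int = 1,
                     scale: float = DESK_SCALE):
    """Reduced-scale survivor grid over population size and replicability
    distance (the N x delta coexistence design)."""
    base = scale_down(ConstantPopulationConfig(), scale)
    return sweep(base, {"n0": list(n_values), "delta": list(delta_values)},
                 replicates, master_seed)


def mutation_series(pmut_values=(0.01, 0.05, 0.1, 0.15), n0: int = 500,
                    replicates: int = 20, master_seed: int = 1,
                    scale: float = 1000):
    """Reduced-scale mutation-rate series (survivors and summed master
    frequency as functions of the per-base error rate)."""
    base = scale_down(ConstantPopulationConfig(n0=n0), scale)
    return sweep(base, {"p_mut": list(pmut_values)}, replicates, master_seed)


def balanced_symmetry_runs(replicates: int = 10, master_seed: int = 1,
                           n0: int = 10_000, scale: float = 100):
    """Symmetry control: balanced-GC masters on a replicability gradient
    with cross-hybridization disabled, where every master regulates only
    itself and all types should persist.  The full design runs 2*10^6
    events; the default reduction shortens only the horizon (100-fold)
    and keeps the full-scale population size — at this landscape's
    self-limited steady state the weakest type holds only a few tens of
    strands even at N = 10^4, so shrinking N would lose it outright."""
    base = ConstantPopulationConfig(
        n0=n0, master_kind="balanced_gc", no_cross_hybridization=True,
        max_repl_events=2_000_000)
    base = scale_down(base, scale)
    runs, agg = sweep(base, {"n0": [n0]}, replicates, master_seed)
    return runs, agg


def parabolic_growth_ensemble(replicates: int = 30, master_seed: int = 1,
                              n_events: int = 1500, init_copies: int = 10,
                              phi: float = 0.005, L: int = 10):
    """Ensemble of single-type growth runs in a resource-rich, closed
    chemostat (no inflow, decay or outflow): an all-G master and its all-C
    complement form a maximum-stability duplex (Eb = 2L), so nearly all
    strands are duplexed and growth is parabolic.

    Returns ``(t_grid, mean_N)``: the ensemble mean total strand count on a
    common time grid.
    """
    from .sequences import MasterSet

    ms = MasterSet(["G" * L], ["C" * L], [phi], generator_kind="random")
    kp = KineticParams(p_mut=0.0, c_decay_ss=0.0, delta=0.0)
    cadence = max(1, n_events // 150)
    cfg = ChemostatConfig(
        T=1, L=L, kinetics=kp, c_in=0.0, c_out=0.0,
        init_copies_per_type=init_copies, init_resources=10**7,
        max_repl_events=(n_events // cadence) * cadence,
        survival_cadence=cadence, survival_window=5 * cadence)
    seeds = replicate_seeds(master_seed, replicates)
    trajs = [run_chemostat(cfg, seed=s, master_set=ms) for s in seeds]
    t_end = min(t.samples["time"].iloc[-1] for t in trajs)
    t_grid = np.linspace(0.0, t_end, 200)
    mean_n = np.mean([np.interp(t_grid, t.samples["time"], t.samples["N"])
                      for t in trajs], axis=0)
    return t_grid, mean_n


def fit_growth_laws(t: np.ndarray, n: np.ndarray, n0: float) -> dict:
    """Least-squares fits of a trajectory to the square-root-growth closed
    form ``N(t) = (k*t/2 + sqrt(N0))**2`` (one parameter) and to the best
    exponential ``a*exp(b*t)`` (two parameters); returns both parameter
    sets and root-mean-square errors."""
    from scipy.optimize import curve_fit, minimize_scalar

    def sqrt_law(tt, k):
        return (k * tt / 2.0 + math.sqrt(n0)) ** 2

    res = minimize_scalar(
        lambda k: float(np.mean((sqrt_law(t, k) - n) ** 2)),
        bounds=(0.0, 10.0), method="bounded",
        options={"xatol": 1e-12})
    k = float(res.x)
    rmse_sqrt = float(np.sqrt(np.mean((sqrt_law(t, k) - n) ** 2)))

    # log-linear start, then direct nonlinear RMSE minimization
    b0, loga0 = np.polyfit(t, np.log(np.maximum(n, 1e-9)), 1)
    try:
        popt, _ = curve_fit(lambda tt, a, b: a * np.exp(b * tt), t, n,
                            p0=(math.exp(loga0), b0), maxfev=20000)
        a_exp, b_exp = float(popt[0]), float(popt[1])
    except RuntimeError:
        a_exp, b_exp = float(math.exp(loga0)), float(b0)
    rmse_exp = float(np.sqrt(np.mean((a_exp * np.exp(b_exp * t) - n) ** 2)))
    return {"k": k, "rmse_sqrt": rmse_sqrt,
            "a": a_exp, "b": b_exp, "rmse_exp": rmse_exp}


def inflow_series(cin_values=(0.1, 0.01), replicates: int = 5,
                  master_seed: int = 1, f: float = 1.0,
                  delta: float = 0.005, c_out: float = 1e-5,
                  events_per_cin: float = 2e5):
    """Chemostat resource-competition series: mean total population size
    and simplex-duplex asymmetry as functions of the monomer inflow rate.
    Run length scales with ``c_in`` so each condition covers a comparable
    span of turnover times."""
    rows = []
    seeds = replicate_seeds(master_seed, replicates)
    for c_in in cin_values:
        events = max(1000, int(round(events_per_cin * c_in / 10.0)) * 10)
        cadence = events // 10
        cfg = ChemostatConfig(
            kinetics=KineticParams(f=f, delta=delta),
            c_in=c_in, c_out=c_out, init_copies_per_type=50,
            max_repl_events=events, survival_cadence=cadence,
            survival_window=5 * cadence)
        for rep, seed in enumerate(seeds):
            traj = run_chemostat(cfg, seed=seed)
            half = traj.samples.iloc[len(traj.samples) // 2:]
            chi = np.nanmean((half["n_simplex"] - half["n_duplex_strands"])
                             / half["N"].replace(0, np.nan))
            surv = assess_survival(traj)
            rows.append({"c_in": c_in, "replicate": rep, "seed": seed,
                         "mean_N": float(half["N"].mean()),
                         "chi": float(chi),
                         "n_survivors": len(surv)})
    return pd.DataFrame(rows)
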