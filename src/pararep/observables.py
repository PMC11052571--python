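"""Trajectory sampling, the survival criterion, and diversity / selectivity
statistics.

A run is summarized by a :class:`TrajectoryRecord`: a tidy table with one
row per sample (taken every ``sample_cadence`` replication events) holding
the per-type master strand counts, the simplex/duplex partition and, for
chemostat runs, the four resource pools.

A master type *survives* a run when its relative strand frequency is at
least the cut-off (default ``1e-3``) in more than one of the six samples
taken every ``cadence`` replication events within the final window of
``5 * cadence`` events before termination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import MasterSet, gc_count

#: survival criterion defaults (full experimental scale)
SURVIVAL_CUTOFF = 1e-3
SURVIVAL_CADENCE = 2000
SURVIVAL_WINDOW = 10_000


@dataclass
class TrajectoryRecord:
    """Sampled time series of one stochastic run."""

    samples: pd.DataFrame
    master_set: MasterSet
    params: dict = field(default_factory=dict)
    counters: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.master_set.T

    def master_columns(self) -> list[str]:
        return [f"m{i + 1}" for i in range(self.T)]

    def frequencies(self) -> pd.DataFrame:
        """Per-type relative strand frequencies (NaN where N = 0)."""
        n = self.samples["N"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.samples[self.master_columns()].to_numpy(float) / n[:, None]
        freq[n == 0] = np.nan
        return pd.DataFrame(freq, columns=self.master_columns(),
                            index=self.samples.index)

    def final_chi(self) -> float:
        row = self.samples.iloc[-1]
        return simplex_duplex_asymmetry(int(row["n_simplex"]),
                                        int(row["n_duplex_strands"]))

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)

    def summary(self, cutoff: float = SURVIVAL_CUTOFF,
                cadence: int | None = None,
                window: int | None = None) -> dict:
        """Survivors, rank statistics, asymmetry and GC statistics."""
        surv = assess_survival(self, cutoff=cutoff, cadence=cadence,
                               window=window)
        rho, rho_max, rho_rand = rank_sum_stats(surv, self.T)
        gc = gc_content_stats(self.master_set, surv)
        mean_chi = float(np.nanmean([
            simplex_duplex_asymmetry(int(r["n_simplex"]),
                                     int(r["n_duplex_strands"]))
            for _, r in self.samples.iterrows()
        ]))
        return {
            "survivors": sorted(i + 1 for i in surv),
            "n_survivors": len(surv),
            "rho": rho, "rho_max": rho_max, "rho_rand": rho_rand,
            "chi_final": self.final_chi(),
            "chi_mean": mean_chi,
            "mean_N": float(self.samples["N"].mean()),
            "gc_stats": gc,
            "counters": self.counters,
        }

    def write_summary(self, path, **kwargs) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(**kwargs), fh, indent=2, default=float)


def make_samples_frame(out_master: np.ndarray, out_extra: np.ndarray,
                       out_time: np.ndarray) -> pd.DataFrame:
    """Assemble the tidy sample table from the compiled core's outputs."""
    T = out_master.shape[1]
    df = pd.DataFrame({
        "event": out_extra[:, 0],
        "time": out_time,
        "n_simplex": out_extra[:, 1],
        "n_duplex_strands": out_extra[:, 2],
    })
    df["N"] = df["n_simplex"] + df["n_duplex_strands"]
    for i in range(T):
        df[f"m{i + 1}"] = out_master[:, i]
    for j, b in enumerate("AUGC"):
        df[f"R_{b}"] = out_extra[:, 3 + j]
    return df


def master_frequency(state, ms: MasterSet, type_i: int) -> float:
    """Relative frequency of master type *type_i* (0-based) in a reference
    :class:`~pararep.ssa.PopulationState`: strands equal to the master or
    its complement, whether free or duplex-resident, over the total strand
    count.  Returns NaN for an empty population."""
    n = state.N
    if n == 0:
        return float("nan")
    targets = {ms.masters[type_i], ms.complements[type_i]}
    count = sum(k for s, k in state.simplex.items() if s in targets)
    for (a, b), k in state.duplexes.items():
        if a in targets:
            count += k
        if b in targets:
            count += k
    return count / n


def assess_survival(traj: TrajectoryRecord,
                    cutoff: float = SURVIVAL_CUTOFF,
                    cadence: int | None = None,
                    window: int | None = None) -> set[int]:
    """Survivor set (0-based type indices) under the steady-state criterion.

    A type survives when its relative frequency is >= *cutoff* in at least
    two of the samples taken every *cadence* replication events within the
    final *window* events of the trajectory.  Defaults are taken from the
    run parameters (scaled runs store their scaled cadence/window).
    """
    cadence = cadence or traj.params.get("survival_cadence", SURVIVAL_CADENCE)
    window = window or traj.params.get("survival_window", SURVIVAL_WINDOW)
    events = traj.samples["event"].to_numpy()
    end = events.max()
    wanted = np.arange(end - window, end + 1, cadence)
    if wanted[0] < 0 or events.min() > wanted[0]:
        raise ValueError(
            f"trajectory does not cover the survival window "
            f"[{end - window}, {end}]")
    mask = np.isin(events, wanted)
    missing = set(wanted) - set(events[mask])
    if missing:
        raise ValueError(f"survival window samples missing: {sorted(missing)}")
    freqs = traj.frequencies().to_numpy(float)[mask]
    hits = np.nansum(freqs >= cutoff, axis=0)
    return {i for i in range(traj.T) if hits[i] >= 2}


def rank_sum_stats(survivors: set[int], T: int) -> tuple[float, float, float]:
    """Sum of replicability ranks of the survivors, its theoretical maximum
    and its random-composition expectation.

    Rank ``i`` (1..T) is the replicability order, rank T the fittest.  For
    ``T_surv`` survivors the maximum is ``T_surv * (2T - T_surv + 1) / 2``
    (= ``T_surv * (21 - T_surv) / 2`` for T = 10) and the expectation under
    a uniformly random survivor subset is ``T_surv * (T + 1) / 2``
    (= ``5.5 * T_surv`` for T = 10).
    """
    t_surv = len(survivors)
    if t_surv == 0:
        return 0.0, 0.0, 0.0
    if not all(0 <= i < T for i in survivors):
        raise ValueError("survivor indices out of range")
    rho = float(sum(i + 1 for i in survivors))
    rho_max = t_surv * (2 * T - t_surv + 1) / 2
    rho_rand = t_surv * (T + 1) / 2
    return rho, rho_max, rho_rand


def simplex_duplex_asymmetry(n_simplex: int, n_duplex_strands: int) -> float:
    """``chi = (N_simplex - N_duplex) / N`` in [-1, 1]; -1 all-duplex,
    +1 all-simplex; NaN for an empty population."""
    n = n_simplex + n_duplex_strands
    if n == 0:
        return float("nan")
    return (n_simplex - n_duplex_strands) / n


def gc_content_stats(ms: MasterSet, survivors: set[int]) -> dict:
    """Mean and SD of the relative GC content of the survived and extinct
    master subsets (NaN where a subset is empty)."""
    gc = ms.gc_contents()
    surv = sorted(survivors)
    ext = [i for i in range(ms.T) if i not in survivors]

    def _stats(idx):
        if not idx:
            return {"mean": float("nan"), "sd": float("nan"), "n": 0}
        vals = gc[idx]
        return {"mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(idx)}

    return {"survived": _stats(surv), "extinct": _stats(ext)}
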