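"""Per-cycle metric assembly and exponential adaptation-kinetics fitting.

Across repeated AB cycles the photophobic response relaxes; the decrease
ratio decays roughly as v(t) = A exp(-t/tau) + B.  The offset B is fitted by
default because the response plateaus at a small nonzero level rather than
vanishing; forcing B = 0 through a plateauing series biases tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .protocol import CYCLE_DURATION_S

TAU_STARTS_H = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class ExpFitResult:
    amplitude: float
    offset: float
    tau: float            # hours
    rss: float
    converged: bool


@dataclass
class CycleSeries:
    """Per-cycle metrics over an 8-cycle protocol."""

    table: pd.DataFrame  # cycle, time_h, decrease_ratio, separation_on,
    #                      separation_off, p_rotation..p_straight

    def __post_init__(self) -> None:
        t = self.table["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("cycle times must be strictly increasing")


def cycle_midpoint_h(cycle: int, cycle_duration_s: float = CYCLE_DURATION_S) -> float:
    """Elapsed time (h) at the midpoint of 1-based ``cycle``."""
    return (cycle - 0.5) * cycle_duration_s / 3600.0


def assemble_cycles(per_cycle: list[dict],
                    cycle_duration_s: float = CYCLE_DURATION_S) -> CycleSeries:
    """Build a CycleSeries from per-cycle metric dicts.

    Each dict carries ``cycle`` (1-based) plus any of ``decrease_ratio``,
    ``separation_on``, ``separation_off`` and type proportions.  Input order
    is irrelevant; missing cycles stay missing (no interpolation).
    """
    if len(per_cycle) < 3:
        raise ValueError("need >= 3 cycles")
    rows = []
    for rec in sorted(per_cycle, key=lambda r: r["cycle"]):
        row = {"cycle": rec["cycle"],
               "time_h": cycle_midpoint_h(rec["cycle"], cycle_duration_s)}
        for k in ("decrease_ratio", "separation_on", "separation_off",
                  "p_rotation", "p_run_tumble", "p_circular", "p_straight"):
            row[k] = rec.get(k, np.nan)
        rows.append(row)
    return CycleSeries(pd.DataFrame(rows))


def fit_exponential(times_h: np.ndarray, values: np.ndarray,
                    with_offset: bool = True) -> ExpFitResult:
    """Least-squares fit of v(t) = A exp(-t/tau) + B.

    Multi-start over a tau grid; for each tau the linear parameters (A, B)
    are profiled exactly, making the noiseless case recover tau to machine
    precision.  Non-convergence is flagged, not raised.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(v)
    t, v = t[ok], v[ok]
    if t.size < 3:
        raise ValueError("need >= 3 finite points")
    if np.allclose(v, v[0]):
        raise ValueError("degenerate (constant) series")

    def linpars(tau: float) -> tuple[float, float, float]:
        e = np.exp(-t / tau)
        if with_offset:
            A = np.column_stack([e, np.ones_like(e)])
        else:
            A = e[:, None]
        sol, *_ = np.linalg.lstsq(A, v, rcond=None)
        resid = v - A @ sol
        b = sol[1] if with_offset else 0.0
        return float(sol[0]), float(b), float(resid @ resid)

    def resid_log_tau(p: np.ndarray) -> np.ndarray:
        tau = np.exp(p[0])
        a, b, _ = linpars(tau)
        return v - (a * np.exp(-t / tau) + b)

    best = None
    for tau0 in TAU_STARTS_H:
        try:
            sol = least_squares(resid_log_tau, x0=[np.log(tau0)], method="lm")
        except Exception:
            continue
        tau = float(np.exp(sol.x[0]))
        a, b, rss = linpars(tau)
        if best is None or rss < best[3]:
            best = (a, b, tau, rss, bool(sol.success))
    if best is None:
        return ExpFitResult(np.nan, np.nan, np.nan, np.inf, converged=False)
    a, b, tau, rss, ok_flag = best
    converged = ok_flag and np.isfinite(tau) and tau > 0
    return ExpFitResult(amplitude=a, offset=b, tau=tau, rss=rss, converged=converged)


def fit_cycle_series(series: CycleSeries, column: str = "decrease_ratio",
                     with_offset: bool = True) -> ExpFitResult:
    df = series.table
    return fit_exponential(df["time_h"].to_numpy(), df[column].to_numpy(),
                           with_offset=with_offset)


def proportions_table(runs: list[CycleSeries],
                      scenario_runs: dict[str, list[pd.Series]] | None = None
                      ) -> pd.DataFrame:
    """Histogram table of motion-type proportions per cycle (mean +- SD
    across replicate runs), optionally extended with named comparative
    scenario columns (e.g. evening / red-only / KH-cultured)."""
    cols = ["p_rotation", "p_run_tumble", "p_circular", "p_straight"]
    frames = [r.table.set_index("cycle")[cols] for r in runs]
    stack = pd.concat(frames, keys=range(len(frames)), names=["run"])
    mean = stack.groupby("cycle").mean()
    sd = stack.groupby("cycle").std(ddof=0)
    out = mean.join(sd, lsuffix="_mean", rsuffix="_sd").reset_index()
    out.insert(0, "condition", out.pop("cycle").map(lambda c: f"cycle_{c}"))
    if scenario_runs:
        extra = []
        for name, props in scenario_runs.items():
            arr = pd.concat(props, axis=1).T  # runs x 4 types
            row = {"condition": name}
            for c in cols:
                row[f"{c}_mean"] = float(arr[c].mean())
                row[f"{c}_sd"] = float(arr[c].std(ddof=0))
            extra.append(row)
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out
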