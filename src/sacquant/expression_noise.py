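"""Constitutive two-stage gene expression model: analytic noise and SSA.

The model is the classic birth-death cascade

    DNA --k_syn_m-->  mRNA --k_deg_m--> 0
    mRNA --k_syn_p--> mRNA + protein --k_deg_p--> 0

with a constitutively active promoter, no bursting, and no cell growth
or division.  At stationarity the mRNA marginal is Poisson with mean
M = k_syn_m/k_deg_m, and the protein coefficient of variation has the
closed form

    CV_P = sqrt( 1/P + (1/M) * k_deg_p / (k_deg_p + k_deg_m) )

so a short mRNA half-life combined with a long protein half-life pushes
protein noise toward the 1/sqrt(P) floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

LN2 = math.log(2.0)

__all__ = [
    "KineticParams",
    "SteadyState",
    "Trajectory",
    "NoiseGridCell",
    "analytic_cv",
    "cv_from_half_lives",
    "rates_from_means",
    "steady_state",
    "feasible",
    "gillespie_simulate",
    "trajectory_stats",
    "noise_grid",
]


@dataclass(frozen=True)
class KineticParams:
    """Four rate constants of the two-stage model.

    k_syn_m: mRNA min^-1; k_deg_m: min^-1;
    k_syn_p: protein mRNA^-1 min^-1; k_deg_p: min^-1.
    """

    k_syn_m: float
    k_deg_m: float
    k_syn_p: float
    k_deg_p: float

    def __post_init__(self) -> None:
        for name in ("k_syn_m", "k_deg_m", "k_syn_p", "k_deg_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_deg_m <= 0 or self.k_deg_p <= 0:
            raise ValueError("degradation rates must be > 0 for a steady state")


@dataclass(frozen=True)
class SteadyState:
    M: float
    P: float


@dataclass
class Trajectory:
    """Piecewise-constant SSA realization: counts hold between event times."""

    times: np.ndarray
    m_counts: np.ndarray
    p_counts: np.ndarray
    seed: int | None = None
    absorbed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "mrna": self.m_counts, "protein": self.p_counts}
        )


@dataclass(frozen=True)
class NoiseGridCell:
    mrna_half_life: float
    protein_half_life: float
    cv: float
    feasible: bool
    classification: str  # 'low' iff cv < threshold


def analytic_cv(P: float, M: float, k_deg_p: float, k_deg_m: float) -> float:
    """Closed-form protein CV of the constitutive two-stage model."""
    if P <= 0 or M <= 0 or k_deg_p <= 0 or k_deg_m <= 0:
        raise ValueError("P, M and degradation rates must be positive")
    return math.sqrt(1.0 / P + (1.0 / M) * k_deg_p / (k_deg_p + k_deg_m))


def cv_from_half_lives(
    P: float, M: float, protein_half_life: float, mrna_half_life: float
) -> float:
    """Analytic CV with half-lives (minutes) instead of rates."""
    return analytic_cv(P, M, LN2 / protein_half_life, LN2 / mrna_half_life)


def rates_from_means(
    M_target: float, P_target: float, k_deg_m: float, k_deg_p: float
) -> KineticParams:
    """Synthesis rates that place the steady state at the given means."""
    if M_target <= 0 or P_target <= 0:
        raise ValueError("target means must be positive")
    return KineticParams(
        k_syn_m=M_target * k_deg_m,
        k_deg_m=k_deg_m,
        k_syn_p=P_target * k_deg_p / M_target,
        k_deg_p=k_deg_p,
    )


def steady_state(params: KineticParams) -> SteadyState:
    M = params.k_syn_m / params.k_deg_m
    return SteadyState(M=M, P=params.k_syn_p * M / params.k_deg_p)


def feasible(
    params: KineticParams, max_syn_m: float = 25.0, max_syn_p: float = 20.0
) -> bool:
    """Physiological-plausibility gate on synthesis rates (inclusive bounds)."""
    return params.k_syn_m <= max_syn_m and params.k_syn_p <= max_syn_p


def gillespie_simulate(
    params: KineticParams,
    t_end: float,
    seed: int | None = None,
    m0: int | None = None,
    p0: int | None = None,
) -> Trajectory:
    """Exact stochastic simulation (direct method) of the four reactions.

    Initial counts default to the rounded steady-state means, which
    shortens the burn-in.  The trajectory is clamped at ``t_end`` (a
    final sample at exactly ``t_end`` repeats the last counts), so
    time-weighted statistics can integrate to the end of the run.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    ss = steady_state(params)
    m = int(round(ss.M)) if m0 is None else int(m0)
    p = int(round(ss.P)) if p0 is None else int(p0)
    if m < 0 or p < 0:
        raise ValueError("initial counts must be nonnegative")

    ksm = params.k_syn_m
    kdm = params.k_deg_m
    ksp = params.k_syn_p
    kdp = params.k_deg_p

    rng = np.random.default_rng(seed)
    log = math.log
    times = [0.0]
    ms = [m]
    ps = [p]
    t = 0.0
    absorbed = False

    BLOCK = 1 << 15
    u_exp: list[float] = []
    u_sel: list[float] = []
    i = BLOCK  # force initial refill
    while True:
        if i >= BLOCK:
            u_exp = rng.random(BLOCK).tolist()
            u_sel = rng.random(BLOCK).tolist()
            i = 0
        a1 = ksm
        a2 = kdm * m
        a3 = ksp * m
        a4 = kdp * p
        a0 = a1 + a2 + a3 + a4
        if a0 == 0.0:
            absorbed = True
            break
        t += -log(1.0 - u_exp[i]) / a0
        if t >= t_end:
            break
        r = u_sel[i] * a0
        i += 1
        if r < a1:
            m += 1
        elif r < a1 + a2:
            m -= 1
        elif r < a1 + a2 + a3:
            p += 1
        else:
            p -= 1
        times.append(t)
        ms.append(m)
        ps.append(p)

    # clamp: hold final state to t_end
    times.append(t_end)
    ms.append(m)
    ps.append(p)

    return Trajectory(
        times=np.asarray(times, dtype=float),
        m_counts=np.asarray(ms, dtype=np.int64),
        p_counts=np.asarray(ps, dtype=np.int64),
        seed=seed,
        absorbed=absorbed,
    )


def trajectory_stats(traj: Trajectory, burn_in: float = 0.0) -> dict[str, float]:
    """Time-weighted moments of an SSA trajectory over [burn_in, t_end].

    SSA event times are irregular, so moments are weighted by the time
    each state is held, not by event count.
    """
    t = traj.times
    t_endpoint = float(t[-1])
    if t_endpoint - burn_in <= 0:
        raise ValueError("burn_in must be smaller than the trajectory duration")
    starts = np.clip(t[:-1], burn_in, None)
    ends = np.clip(t[1:], burn_in, None)
    w = ends - starts
    total = w.sum()
    out: dict[str, float] = {}
    for key, vals in (("M", traj.m_counts[:-1]), ("P", traj.p_counts[:-1])):
        v = vals.astype(float)
        mean = float((w * v).sum() / total)
        var = float((w * (v - mean) ** 2).sum() / total)
        out[f"mean_{key}"] = mean
        out[f"var_{key}"] = var
        out[f"cv_{key}"] = math.sqrt(var) / mean if mean > 0 else math.nan
    return out


def default_burn_in(params: KineticParams, mult: float = 10.0) -> float:
    """Relaxation-based burn-in: ``mult`` times the slowest lifetime."""
    return mult * max(1.0 / params.k_deg_m, 1.0 / params.k_deg_p)


def noise_grid(
    mrna_half_lives,
    protein_half_lives,
    M_target: float,
    P_target: float = 6000.0,
    cv_threshold: float = 0.06,
    max_syn_m: float = 25.0,
    max_syn_p: float = 20.0,
) -> list[NoiseGridCell]:
    """Analytic protein CV over a grid of mRNA and protein half-lives.

    Each cell is classified 'low' when CV < ``cv_threshold``; cells whose
    implied synthesis rates exceed the plausibility bounds are marked
    infeasible (the CV is still reported).
    """
    cells: list[NoiseGridCell] = []
    for hl_m in mrna_half_lives:
        for hl_p in protein_half_lives:
            if hl_m <= 0 or hl_p <= 0:
                raise ValueError("half-lives must be positive")
            params = rates_from_means(M_target, P_target, LN2 / hl_m, LN2 / hl_p)
            cv = analytic_cv(P_target, M_target, params.k_deg_p, params.k_deg_m)
            cells.append(
                NoiseGridCell(
                    mrna_half_life=float(hl_m),
                    protein_half_life=float(hl_p),
                    cv=cv,
                    feasible=feasible(params, max_syn_m, max_syn_p),
                    classification="low" if cv < cv_threshold else "high",
                )
            )
    return cells


def grid_frame(cells: list[NoiseGridCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])
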