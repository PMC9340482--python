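"""mRNA half-life estimation from metabolic-labeling decay time courses.

Workflow: qPCR Ct values are converted to efficiency-corrected relative
expression (Pfaffl-style normalization against the geometric mean of
reference amplicons), each decay series is fit with one of three
exponential models,

    fit1: y = 2^(-t/HL)
    fit2: y = eff * 2^(-t/HL) + (1 - eff)
    fit3: y = mRNA0 * 2^(-t/HL)          (time-0 points excluded)

and genotype contrasts come from a linearized hierarchical model

    ln y = ln mRNA0 + (-ln2/HL) * t

with fixed effects time, genotype and their interaction and random
slopes + intercepts per experimental replicate.  HL = -ln2/slope, where
the slope for the reference genotype is the time coefficient and for the
other genotype the sum of time and interaction coefficients.  Confidence
intervals come from a parametric bootstrap of the fitted model.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

__all__ = [
    "StandardCurve",
    "DecaySeries",
    "DecayFit",
    "HierarchicalFit",
    "efficiency_from_standard_curve",
    "relative_expression",
    "fit_decay",
    "fit_hierarchical",
    "half_life_difference",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class StandardCurve:
    dilutions: tuple[float, ...]
    cts: tuple[float, ...]
    slope: float  # cycles per log-unit of input
    intercept: float
    efficiency: float
    log_base: float
    r_squared: float


@dataclass
class DecaySeries:
    """One replicate's expression-vs-time measurements for one gene."""

    gene: str
    genotype: str
    replicate: str
    times: np.ndarray  # minutes
    rel_expr: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rel_expr = np.asarray(self.rel_expr, dtype=float)
        if self.times.shape != self.rel_expr.shape:
            raise ValueError("times and rel_expr must have equal length")
        if (np.diff(self.times) < 0).any():
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.rel_expr = self.rel_expr[order]
        if (self.times < 0).any():
            raise ValueError("negative time points")


@dataclass
class DecayFit:
    model: str
    half_life: float
    aux: dict = field(default_factory=dict)
    ci: tuple[float, float] | None = None
    n_points: int = 0
    converged: bool = True
    message: str = ""


@dataclass
class HierarchicalFit:
    """Joint log-linear fit of two genotypes with genotype contrast."""

    reference_genotype: str
    other_genotype: str
    time_coef: float          # slope for the reference (coded-0) genotype
    interaction_coef: float
    half_lives: dict          # genotype -> DecayFit
    hl_difference: float      # other - reference, minutes
    used_random_effects: bool
    n_points: int
    converged: bool = True
    coefs: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)       # name -> (lo, hi)
    significant: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# qPCR preprocessing


def efficiency_from_standard_curve(
    dilutions: Sequence[float], cts: Sequence[float], log_base: float = 10.0
) -> StandardCurve:
    """Amplification efficiency from a dilution standard curve.

    Fits Ct against log_base(relative input) by least squares;
    efficiency = base^(-1/slope) - 1, which is invariant to the base
    chosen.  A perfect doubling chemistry gives slope -3.32 on log10
    (one cycle per twofold input) and efficiency 1.0.
    """
    d = np.asarray(dilutions, dtype=float)
    c = np.asarray(cts, dtype=float)
    if d.size < 3:
        raise ValueError("need >= 3 (dilution, Ct) pairs")
    if (d <= 0).any():
        raise ValueError("dilutions must be positive")
    x = np.log(d) / np.log(log_base)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance dilutions")
    slope, intercept = np.polyfit(x, c, 1)
    pred = slope * x + intercept
    ss_res = float(((c - pred) ** 2).sum())
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    eff = log_base ** (-1.0 / slope) - 1.0
    return StandardCurve(
        dilutions=tuple(d),
        cts=tuple(c),
        slope=float(slope),
        intercept=float(intercept),
        efficiency=float(eff),
        log_base=float(log_base),
        r_squared=r2,
    )


def relative_expression(
    ct_target_sample: float,
    ct_target_control: float,
    eff_target: float,
    refs: Sequence[tuple[float, float, float]],
) -> float:
    """Efficiency-corrected expression ratio (Pfaffl-style).

    ``refs`` is a list of ``(ct_ref_sample, ct_ref_control, eff_ref)``
    tuples; the denominator is the geometric mean of the reference
    terms.  With all efficiencies equal to 1 this reduces to the classic
    2^(-ddCt).
    """
    if not refs:
        raise ValueError("at least one reference amplicon is required")
    for eff in [eff_target] + [r[2] for r in refs]:
        if not (0.0 < eff <= 1.0):
            raise ValueError("efficiencies must lie in (0, 1]")
    num = (eff_target + 1.0) ** (ct_target_control - ct_target_sample)
    log_den = 0.0
    for ct_s, ct_c, eff in refs:
        log_den += (ct_c - ct_s) * math.log(eff + 1.0)
    den = math.exp(log_den / len(refs))
    return num / den


def average_technical_replicates(cts: Sequence[float]) -> float:
    """Technical qPCR replicates are averaged on the Ct scale."""
    return float(np.mean(np.asarray(cts, dtype=float)))


# ---------------------------------------------------------------------------
# nonlinear decay fits


def _model_curve(model: str, t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    hl = math.exp(theta[0])
    decay = 2.0 ** (-t / hl)
    if model == "fit1":
        return decay
    if model == "fit2":
        eff = theta[1]
        return eff * decay + (1.0 - eff)
    if model == "fit3":
        mrna0 = math.exp(theta[1])
        return mrna0 * decay
    raise ValueError(f"unknown model {model!r}")


def fit_decay(series: DecaySeries, model: str = "fit3",
              log_residuals: bool = False) -> DecayFit:
    """Nonlinear least-squares fit of one decay model to one series.

    HL (and fit3's mRNA0) are kept positive through a log
    parameterization; fit2's efficiency is bounded in (0, 1].  fit3
    drops time-0 measurements, treating the level at t=0 as the free
    amplitude mRNA0 (this absorbs non-instantaneous labeling).

    ``log_residuals=True`` minimizes residuals of log expression
    instead of raw expression — appropriate when measurement noise is
    multiplicative, and markedly more stable for slowly decaying
    transcripts whose late-timepoint signal is near zero.  The default
    is plain NLS on the natural scale.
    """
    t = series.times
    y = series.rel_expr
    if model == "fit3":
        keep = t > 0
        t, y = t[keep], y[keep]
        if t.size < 2:
            raise ValueError("fit3 needs >= 2 points with t > 0")
    else:
        if t.size < 2:
            raise ValueError(f"{model} needs >= 2 points")

    # initial HL from a log-linear slope on the positive part of the curve
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log2(y[pos]), 1)[0]
        hl0 = -1.0 / slope if slope < 0 else float(np.ptp(t)) or 10.0
    else:
        hl0 = 10.0
    hl0 = min(max(hl0, 1e-3), 1e5)

    if model == "fit1":
        x0 = np.array([math.log(hl0)])
        lb, ub = [-np.inf], [np.inf]
    elif model == "fit2":
        x0 = np.array([math.log(hl0), 0.9])
        lb, ub = [-np.inf, 1e-9], [np.inf, 1.0]
    else:
        y0 = float(y[0]) if y[0] > 0 else 1.0
        x0 = np.array([math.log(hl0), math.log(y0)])
        lb, ub = [-np.inf, -np.inf], [np.inf, np.inf]

    if log_residuals:
        if (y <= 0).any():
            raise ValueError("log-residual fitting needs positive expression")

        def resid(th):
            pred = _model_curve(model, t, th)
            if (pred <= 0).any():
                return np.full_like(y, 1e6)
            return np.log(pred) - np.log(y)
    else:
        def resid(th):
            return _model_curve(model, t, th) - y

    res = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    hl = math.exp(res.x[0])
    aux: dict = {}
    if model == "fit2":
        aux["efficiency"] = float(res.x[1])
    elif model == "fit3":
        aux["mrna0"] = math.exp(res.x[1])
    return DecayFit(
        model=model,
        half_life=hl,
        aux=aux,
        n_points=int(t.size),
        converged=bool(res.success),
        message=res.message if not res.success else "",
    )


# ---------------------------------------------------------------------------
# hierarchical (mixed-model) fit and genotype contrast


def half_life_difference(time_coef: float, interaction_coef: float) -> float:
    """Half-life difference implied by the log-linear model coefficients.

    Equals HL(coded-1 genotype) - HL(coded-0 genotype):
    ln2 * i / (t * (t + i)) with t the time coefficient and i the
    interaction coefficient.
    """
    if time_coef == 0 or time_coef + interaction_coef == 0:
        raise ValueError("time coefficient and combined slope must be nonzero")
    return LN2 * interaction_coef / (time_coef * (time_coef + interaction_coef))


def _series_frame(series_set: Iterable[DecaySeries]) -> pd.DataFrame:
    rows = []
    for s in series_set:
        for t, y in zip(s.times, s.rel_expr):
            rows.append((s.gene, s.genotype, s.replicate, float(t), float(y)))
    df = pd.DataFrame(rows, columns=["gene", "genotype", "replicate", "time", "y"])
    df = df[df["time"] > 0].copy()  # linearized model excludes t = 0
    if (df["y"] <= 0).any():
        raise ValueError("relative expression must be positive for the log-linear fit")
    df["logy"] = np.log(df["y"])
    return df


def _fit_coded(df: pd.DataFrame, reference: str, use_random_effects: bool):
    """Fit ln(y) ~ time * genotype with the given genotype coded 0.

    Returns (time_coef, interaction_coef, result, used_re).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    work = df.copy()
    work["g"] = (work["genotype"] != reference).astype(float)
    formula = "logy ~ time * g"
    if use_random_effects and work["replicate"].nunique() >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(formula, work, groups=work["replicate"],
                                 re_formula="~time")
                fit = md.fit(reml=True, method="lbfgs")
            if np.isfinite(fit.fe_params).all():
                return (
                    float(fit.fe_params["time"]),
                    float(fit.fe_params["time:g"]),
                    fit,
                    True,
                )
        except Exception as exc:  # singular fit, LinAlgError, ...
            logger.warning("mixed-model fit failed (%s); falling back to "
                           "fixed effects with replicate indicator", exc)
    extra = " + C(replicate)" if work["replicate"].nunique() >= 2 else ""
    fit = smf.ols(formula + extra, work).fit()
    return float(fit.params["time"]), float(fit.params["time:g"]), fit, False


def fit_hierarchical(
    series_set: Iterable[DecaySeries],
    reference_genotype: str | None = None,
    use_random_effects: bool = True,
) -> HierarchicalFit:
    """Joint log-linear decay fit for two genotypes.

    Fixed effects: time, genotype, time x genotype; random slopes and
    intercepts per replicate (falling back to a replicate fixed effect,
    flagged, when the mixed fit is singular or fails).  The model is fit
    with each genotype coded 0 in turn, and each genotype's half-life is
    read off the time coefficient of its own coding as HL = -ln2/slope.
    """
    series_list = list(series_set)
    df = _series_frame(series_list)
    genos = list(dict.fromkeys(df["genotype"]))
    if len(genos) != 2:
        raise ValueError(f"need exactly 2 genotypes, got {genos}")
    if reference_genotype is None:
        reference_genotype = genos[0]
    if reference_genotype not in genos:
        raise ValueError(f"reference genotype {reference_genotype!r} not in data")
    other = next(g for g in genos if g != reference_genotype)

    half_lives: dict[str, DecayFit] = {}
    results = {}
    for coded0 in (reference_genotype, other):
        tc, ic, fit, used_re = _fit_coded(df, coded0, use_random_effects)
        results[coded0] = (tc, ic, fit, used_re)
        hl = -LN2 / tc
        half_lives[coded0] = DecayFit(
            model="hierarchical", half_life=hl,
            aux={"time_coef": tc, "interaction_coef": ic},
            n_points=int((df["genotype"] == coded0).sum()),
            converged=math.isfinite(hl) and hl > 0,
        )

    tc, ic, _, used_re = results[reference_genotype]
    return HierarchicalFit(
        reference_genotype=reference_genotype,
        other_genotype=other,
        time_coef=tc,
        interaction_coef=ic,
        half_lives=half_lives,
        hl_difference=half_life_difference(tc, ic),
        used_random_effects=used_re,
        n_points=len(df),
        converged=all(f.converged for f in half_lives.values()),
        coefs={"time": tc, "interaction": ic},
    )


# ---------------------------------------------------------------------------
# bootstrap


def _simulate_from_fit(
    df: pd.DataFrame,
    reference: str,
    fit_result,
    used_re: bool,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Parametric draw of new log-responses from the fitted model."""
    work = df.copy()
    work["g"] = (work["genotype"] != reference).astype(float)
    X = np.column_stack(
        [np.ones(len(work)), work["time"], work["g"], work["time"] * work["g"]]
    )
    if used_re:
        fe = fit_result.fe_params[["Intercept", "time", "g", "time:g"]].to_numpy()
        mu = X @ fe
        cov = np.asarray(fit_result.cov_re)
        scale = float(fit_result.scale)
        for rep, idx in work.groupby("replicate").groups.items():
            b = rng.multivariate_normal(np.zeros(cov.shape[0]), cov,
                                        method="cholesky")
            rows = work.index.get_indexer(idx)
            mu[rows] += b[0] + b[1] * work.loc[idx, "time"].to_numpy()
        sigma = math.sqrt(scale)
    else:
        params = fit_result.params
        mu = (
            params.get("Intercept", 0.0)
            + params["time"] * work["time"].to_numpy()
            + params["g"] * work["g"].to_numpy()
            + params["time:g"] * (work["time"] * work["g"]).to_numpy()
        )
        # replicate fixed effects, if present in the fallback model
        for name, val in params.items():
            if name.startswith("C(replicate)"):
                level = name.split("T.")[-1].rstrip("]")
                mu = mu + val * (work["replicate"].astype(str) == level).to_numpy()
        sigma = math.sqrt(float(fit_result.scale)) if hasattr(fit_result, "scale") \
            else float(np.std(fit_result.resid, ddof=1))
    work["logy"] = mu + rng.normal(0.0, sigma, size=len(work))
    work["y"] = np.exp(work["logy"])
    return work


def bootstrap_ci(
    series_set: Iterable[DecaySeries],
    reference_genotype: str | None = None,
    n_boot: int = 10000,
    seed: int | None = None,
    level: float = 0.95,
    flavor: str = "parametric",
    use_random_effects: bool = True,
) -> HierarchicalFit:
    """Hierarchical fit with bootstrap confidence intervals.

    ``flavor='parametric'`` simulates new responses from the fitted
    model (fixed effects + replicate random effects + residual noise)
    and refits; ``flavor='cluster'`` resamples replicates with
    replacement.  Percentile intervals are reported for the time and
    interaction coefficients, both half-lives, and the half-life
    difference; a contrast is called significant when the interval for
    the interaction (or the HL difference) excludes 0.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    series_list = list(series_set)
    base = fit_hierarchical(series_list, reference_genotype,
                            use_random_effects=use_random_effects)
    ref = base.reference_genotype
    df = _series_frame(series_list)
    tc0, ic0, fit_result, used_re = _fit_coded(df, ref, use_random_effects)

    rng = np.random.default_rng(seed)
    draws = {k: [] for k in ("time", "interaction", "hl_ref", "hl_other", "hl_diff")}
    reps = df["replicate"].unique()
    for _ in range(n_boot):
        if flavor == "parametric":
            sim = _simulate_from_fit(df, ref, fit_result, used_re, rng)
        elif flavor == "cluster":
            chosen = rng.choice(reps, size=len(reps), replace=True)
            parts = []
            for j, rep in enumerate(chosen):
                part = df[df["replicate"] == rep].copy()
                part["replicate"] = f"boot{j}"
                parts.append(part)
            sim = pd.concat(parts, ignore_index=True)
        else:
            raise ValueError("flavor must be 'parametric' or 'cluster'")
        try:
            tc, ic, _, _ = _fit_coded(sim, ref, use_random_effects)
        except Exception:
            continue
        if tc == 0 or tc + ic == 0:
            continue
        draws["time"].append(tc)
        draws["interaction"].append(ic)
        draws["hl_ref"].append(-LN2 / tc)
        draws["hl_other"].append(-LN2 / (tc + ic))
        draws["hl_diff"].append(half_life_difference(tc, ic))

    alpha = (1.0 - level) / 2.0
    ci = {}
    for key, vals in draws.items():
        arr = np.asarray(vals)
        if arr.size == 0:
            ci[key] = (math.nan, math.nan)
        else:
            ci[key] = tuple(np.quantile(arr, [alpha, 1.0 - alpha]))
    base.ci = ci
    base.significant = {
        "interaction": not (ci["interaction"][0] <= 0.0 <= ci["interaction"][1]),
        "hl_difference": not (ci["hl_diff"][0] <= 0.0 <= ci["hl_diff"][1]),
    }
    base.half_lives[ref].ci = ci["hl_ref"]
    base.half_lives[base.other_genotype].ci = ci["hl_other"]
    return base
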