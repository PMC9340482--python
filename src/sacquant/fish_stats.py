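"""Statistics for single-molecule FISH count and spot tables.

Consumes per-cell mRNA counts (with cell length) and per-spot 3D
coordinates/intensities produced upstream by spot-detection software;
provides Poisson fits to count distributions, log-link count regression
against cell length with genotype ratios, nearest-neighbor two-color
colocalization with an empirically derived distance cutoff, a
spot-intensity dimer (double-intensity) test, and the random-pairing
expectation for tag-directed pull-downs of dimerizing proteins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import chi2, gaussian_kde, poisson

logger = logging.getLogger(__name__)

__all__ = [
    "PoissonFit",
    "CountModelFit",
    "ColocalizationResult",
    "IntensityPeakResult",
    "PairingExpectation",
    "fit_poisson_counts",
    "fit_count_regression",
    "nn_distances",
    "colocalization_cutoff",
    "classify_colocalization",
    "intensity_peak_test",
    "expected_pulldown_ratio",
    "simulate_random_pairing",
]


@dataclass
class PoissonFit:
    lam: float
    n: int
    chi2_stat: float | None = None
    p_value: float | None = None
    df: int | None = None

    def pmf(self, k) -> np.ndarray:
        return poisson.pmf(k, self.lam)


@dataclass
class CountModelFit:
    coefficients: dict
    genotype_ratio: float
    ratio_ci: tuple[float, float] | None
    used_random_effects: bool
    include_interaction: bool
    lrt_p: float | None = None
    reference_genotype: str = ""
    other_genotype: str = ""


@dataclass
class ColocalizationResult:
    cutoff: float
    table: pd.DataFrame  # columns: cell_id?, channel?, distance, colocalized
    fractions: dict      # channel (or 'all') -> colocalized fraction


@dataclass
class IntensityPeakResult:
    peak_ref: float
    peak_test: float
    peak_ratio: float
    doubled: bool


@dataclass(frozen=True)
class PairingExpectation:
    """Random-pairing expectation for a tag-directed dimer pull-down.

    With tagged monomer fraction p, dimer classes occur at p^2,
    2p(1-p), (1-p)^2; a pull-down on the tag captures every dimer with
    at least one tagged subunit, so the tagged:untagged subunit ratio in
    the pull-down is (2p^2 + 2p(1-p)) / (2p(1-p)) = 1/(1-p) = 1 + r.
    """

    input_ratio: float
    tagged_fraction: float
    expected_pulldown_ratio: float


# ---------------------------------------------------------------------------
# count distributions and regression


def fit_poisson_counts(counts: Sequence[int], gof: bool = True,
                       min_expected: float = 5.0) -> PoissonFit:
    """Maximum-likelihood Poisson fit to per-cell mRNA counts.

    The MLE is the sample mean.  The goodness-of-fit chi-square pools
    sparse tail bins (expected < ``min_expected``) and uses
    df = bins - 2 (one estimated parameter).
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 1:
        raise ValueError("need >= 1 count")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be nonnegative integers")
    lam = float(c.mean())
    out = PoissonFit(lam=lam, n=int(c.size))
    if not gof or lam == 0:
        return out

    kmax = int(c.max())
    obs = np.bincount(c.astype(int), minlength=kmax + 1).astype(float)
    exp = poisson.pmf(np.arange(kmax + 1), lam) * c.size
    # final open bin for k > kmax
    obs = np.append(obs, 0.0)
    exp = np.append(exp, c.size * poisson.sf(kmax, lam))
    # pool from the right tail until expected counts are adequate
    while exp.size > 2 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        obs, exp = obs[:-1], exp[:-1]
    # pool from the left as well
    while exp.size > 2 and exp[0] < min_expected:
        exp[1] += exp[0]
        obs[1] += obs[0]
        obs, exp = obs[1:], exp[1:]
    df = int(exp.size) - 2
    stat = float(((obs - exp) ** 2 / exp).sum())
    out.chi2_stat = stat
    out.df = df
    out.p_value = float(chi2.sf(stat, df)) if df > 0 else None
    return out


def _center_log_length(lengths: np.ndarray) -> np.ndarray:
    ll = np.log(lengths)
    return ll - ll.mean()


def fit_count_regression(
    cells: pd.DataFrame,
    genotype_pair: tuple[str, str],
    count_col: str = "count_whole",
    include_interaction: str = "auto",
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    use_random_effects: str = "auto",
) -> CountModelFit:
    """Poisson log-link regression of per-cell counts on cell length.

    Cell length is natural-log transformed and centered so that a cell
    of average length scores zero; the genotype coefficient, once
    exponentiated, is then the ratio of expected RNA levels between the
    two genotypes at average cell length.  In ``include_interaction=
    'auto'`` mode a likelihood-ratio test (chi-square, P < 0.05) decides
    whether the length x genotype interaction is kept.  The ratio CI is
    a percentile bootstrap over cells resampled within genotype.

    Replicate/image random effects in the style of a Poisson GLMM are
    attempted only when a ``replicate_id`` column with >= 2 levels is
    present; otherwise (or on failure) a plain GLM with replicate fixed
    effects is used and ``used_random_effects`` is False.
    """
    import statsmodels.api as sm

    ref, alt = genotype_pair
    work = cells[cells["genotype"].isin([ref, alt])].copy()
    if work["genotype"].nunique() < 2:
        raise ValueError("both genotypes must be present")
    if (work["length"] <= 0).any():
        raise ValueError("cell lengths must be positive")
    work["g"] = (work["genotype"] == alt).astype(float)
    work["cll"] = _center_log_length(work["length"].to_numpy(dtype=float))
    y = work[count_col].to_numpy(dtype=float)
    if (y == 0).all():
        raise ValueError("all counts are zero")
    for geno, grp in work.groupby("genotype"):
        if (grp[count_col] == 0).all():
            logger.warning("genotype %s has all-zero counts; ratio is one-sided",
                           geno)

    def design(w: pd.DataFrame, interaction: bool) -> np.ndarray:
        cols = [np.ones(len(w)), w["cll"].to_numpy(), w["g"].to_numpy()]
        if interaction:
            cols.append((w["cll"] * w["g"]).to_numpy())
        return np.column_stack(cols)

    def fit_glm(w: pd.DataFrame, interaction: bool):
        X = design(w, interaction)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(w[count_col].to_numpy(dtype=float), X,
                          family=sm.families.Poisson()).fit()

    # interaction decision
    lrt_p = None
    if include_interaction == "auto":
        f0 = fit_glm(work, False)
        f1 = fit_glm(work, True)
        stat = 2.0 * (f1.llf - f0.llf)
        lrt_p = float(chi2.sf(max(stat, 0.0), 1))
        interaction = lrt_p < 0.05
    elif include_interaction in ("on", True):
        interaction = True
    elif include_interaction in ("off", False):
        interaction = False
    else:
        raise ValueError("include_interaction must be 'auto', 'on' or 'off'")

    used_re = False
    if (
        use_random_effects in ("auto", "on")
        and "replicate_id" in work.columns
        and work["replicate_id"].nunique() >= 2
    ):
        try:
            from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

            work["replicate_id"] = work["replicate_id"].astype(str)
            inter = " + cll:g" if interaction else ""
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = PoissonBayesMixedGLM.from_formula(
                    f"{count_col} ~ cll + g{inter}",
                    {"rep": "0 + C(replicate_id)",
                     "rep_slope": "0 + C(replicate_id):cll"},
                    work,
                )
                res = md.fit_map()
            params = dict(zip(md.exog_names, res.fe_mean))
            used_re = True
        except Exception as exc:
            logger.warning("Poisson mixed model failed (%s); falling back to GLM",
                           exc)
    if not used_re:
        res = fit_glm(work, interaction)
        names = ["intercept", "log_length", "genotype"] + (
            ["interaction"] if interaction else []
        )
        params = dict(zip(names, res.params))
        params = {
            "Intercept": params["intercept"],
            "cll": params["log_length"],
            "g": params["genotype"],
            **({"cll:g": params["interaction"]} if interaction else {}),
        }

    g_coef = params["g"]
    ratio = math.exp(g_coef)

    ratio_ci = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        idx_by_geno = [work.index[work["g"] == v].to_numpy() for v in (0.0, 1.0)]
        draws = []
        for _ in range(n_boot):
            take = np.concatenate(
                [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_geno]
            )
            wb = work.loc[take]
            try:
                rb = fit_glm(wb, interaction)
            except Exception:
                continue
            draws.append(float(rb.params[2]))
        if draws:
            alpha = (1.0 - level) / 2.0
            lo, hi = np.quantile(np.asarray(draws), [alpha, 1.0 - alpha])
            ratio_ci = (math.exp(lo), math.exp(hi))

    coef_out = {
        "intercept": params["Intercept"],
        "log_length": params["cll"],
        "genotype": g_coef,
    }
    if interaction:
        coef_out["interaction"] = params.get("cll:g", math.nan)
    return CountModelFit(
        coefficients=coef_out,
        genotype_ratio=ratio,
        ratio_ci=ratio_ci,
        used_random_effects=used_re,
        include_interaction=interaction,
        lrt_p=lrt_p,
        reference_genotype=ref,
        other_genotype=alt,
    )


# ---------------------------------------------------------------------------
# colocalization


def _spot_coords(spots: pd.DataFrame) -> np.ndarray:
    return spots[["x", "y", "z"]].to_numpy(dtype=float)


def nn_distances(
    spots_a: pd.DataFrame,
    spots_b: pd.DataFrame,
    per_cell: bool = True,
    symmetric: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Nearest-neighbor 3D distances from each spot in A to channel B.

    Coordinates are Euclidean in physical units (µm); distances are
    computed within the same cell when ``per_cell`` (cells lacking one
    channel are skipped and counted).  ``symmetric=True`` also maps each
    B spot to its nearest A.  Returns ``(distances, n_skipped_cells)``;
    the frame has columns cell_id, from_channel, distance.
    """
    frames = []
    skipped = 0

    def one_direction(sa: pd.DataFrame, sb: pd.DataFrame, label: str):
        nonlocal skipped
        if per_cell:
            cells_a = set(sa["cell_id"])
            cells_b = set(sb["cell_id"])
            for cid in sorted(cells_a | cells_b, key=str):
                a = sa[sa["cell_id"] == cid]
                b = sb[sb["cell_id"] == cid]
                if len(a) == 0 or len(b) == 0:
                    skipped += 1
                    continue
                d, _ = cKDTree(_spot_coords(b)).query(_spot_coords(a))
                frames.append(pd.DataFrame(
                    {"cell_id": cid, "from_channel": label, "distance": d}))
        else:
            d, _ = cKDTree(_spot_coords(sb)).query(_spot_coords(sa))
            frames.append(pd.DataFrame(
                {"cell_id": "all", "from_channel": label, "distance": d}))

    one_direction(spots_a, spots_b, "a")
    if symmetric:
        one_direction(spots_b, spots_a, "b")
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["cell_id", "from_channel", "distance"])
    return out, skipped


def colocalization_cutoff(
    control_distances: Sequence[float], method: str = "quantile", q: float = 0.95
) -> dict:
    """Distance cutoff from a same-target two-color control experiment.

    The control hybridizes two probe sets against the same transcript,
    so its nearest-neighbor distances reflect chromatic registration and
    localization error only; the cutoff is a quantile (default 95th) of
    that distribution.  Method and quantile are recorded in the output.
    """
    d = np.asarray(control_distances, dtype=float)
    if d.size < 20:
        raise ValueError(f"need >= 20 control distances, got {d.size}")
    if method != "quantile":
        raise ValueError("only the 'quantile' method is implemented")
    return {
        "cutoff": float(np.quantile(d, q)),
        "method": method,
        "q": float(q),
        "n_control": int(d.size),
    }


def classify_colocalization(distances: pd.DataFrame | Sequence[float],
                            cutoff: float) -> ColocalizationResult:
    """Classify each spot as colocalized (distance <= cutoff) or unpaired."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(distances, pd.DataFrame):
        table = distances.copy()
    else:
        table = pd.DataFrame({"distance": np.asarray(distances, dtype=float)})
    table["colocalized"] = table["distance"] <= cutoff
    fractions: dict[str, float] = {"all": float(table["colocalized"].mean())}
    if "from_channel" in table.columns:
        for ch, grp in table.groupby("from_channel"):
            fractions[str(ch)] = float(grp["colocalized"].mean())
    return ColocalizationResult(cutoff=float(cutoff), table=table,
                                fractions=fractions)


def apply_chromatic_offset(spots: pd.DataFrame, offset_um) -> pd.DataFrame:
    """Apply a precomputed per-channel (x, y, z) offset before distances."""
    out = spots.copy()
    for axis, val in zip(("x", "y", "z"), offset_um):
        out[axis] = out[axis] + val
    return out


# ---------------------------------------------------------------------------
# intensity dimer test


def intensity_peak_test(
    intensities_ref_single: Sequence[float],
    intensities_test: Sequence[float],
    grid_points: int = 512,
) -> IntensityPeakResult:
    """Mode-based double-intensity test for co-translational dimer spots.

    Kernel densities (Silverman bandwidth) are estimated on
    log-intensities and the mode located on a fixed grid; the test group
    is called 'doubled' when its peak exceeds the reference peak by more
    than sqrt(2)-fold (the log-scale midpoint between 1x and 2x).  A
    mode is deliberately robust: a mixture of 1x and 2x spots keeps its
    peak near 1x, so 'doubled' means the bulk of spots shifted.
    """
    ref = np.asarray(intensities_ref_single, dtype=float)
    test = np.asarray(intensities_test, dtype=float)
    for name, arr in (("reference", ref), ("test", test)):
        if arr.size < 50:
            raise ValueError(f"need >= 50 {name} spots, got {arr.size}")
        if (arr <= 0).any():
            raise ValueError("intensities must be positive")

    def mode_of(arr: np.ndarray) -> float:
        la = np.log(arr)
        if np.ptp(la) == 0:
            return float(arr[0])
        kde = gaussian_kde(la, bw_method="silverman")
        grid = np.linspace(la.min(), la.max(), grid_points)
        dens = kde(grid)
        return float(np.exp(grid[np.argmax(dens)]))

    peak_ref = mode_of(ref)
    peak_test = mode_of(test)
    ratio = peak_test / peak_ref
    return IntensityPeakResult(
        peak_ref=peak_ref,
        peak_test=peak_test,
        peak_ratio=ratio,
        doubled=bool(ratio > math.sqrt(2.0)),
    )


# ---------------------------------------------------------------------------
# random-pairing pull-down model


def expected_pulldown_ratio(input_ratio: float) -> PairingExpectation:
    """Expected tagged:untagged ratio in a tag-directed dimer pull-down.

    Under random pairing with homo- and heterodimers equally likely, an
    input ratio r gives a pull-down ratio of 1 + r: a 1:1 input yields
    2:1, a 3:1 input yields 4:1.
    """
    r = float(input_ratio)
    if r <= 0:
        raise ValueError("input ratio must be positive")
    p = r / (1.0 + r)
    return PairingExpectation(
        input_ratio=r, tagged_fraction=p, expected_pulldown_ratio=1.0 + r
    )


def simulate_random_pairing(
    n_monomers: int, tagged_fraction: float, seed: int | None = None
) -> float:
    """Monte-Carlo check of the pull-down expectation.

    ``n_monomers`` monomers (a fixed ``round(p * n)`` of them tagged)
    are matched uniformly at random into dimers; returns the empirical
    tagged:untagged subunit ratio among tag-containing dimers
    (``inf`` when no heterodimers form).
    """
    if n_monomers < 2 or n_monomers % 2 != 0:
        raise ValueError("n_monomers must be even and >= 2")
    if not (0.0 <= tagged_fraction <= 1.0):
        raise ValueError("tagged_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_tagged = int(round(tagged_fraction * n_monomers))
    tags = np.zeros(n_monomers, dtype=bool)
    tags[:n_tagged] = True
    rng.shuffle(tags)
    pairs = tags.reshape(-1, 2)
    per_pair = pairs.sum(axis=1)
    n_tt = int((per_pair == 2).sum())
    n_tu = int((per_pair == 1).sum())
    tagged_subunits = 2 * n_tt + n_tu
    untagged_subunits = n_tu
    if untagged_subunits == 0:
        return math.inf
    return tagged_subunits / untagged_subunits
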