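"""Seeded generators for every input format the analysis modules consume.

Each generator draws from its own RNG stream derived from
``(seed, generator-name)``, so adding a generator never perturbs the
output of another, and identical arguments always yield byte-identical
outputs.  The generators plant known effects (codon-stability
correlations, decay half-lives, genotype count ratios, colocalized spot
fractions, qPCR ratios) that the corresponding analysis module should
recover — the package's core regression test.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, START_CODON
from .codon_metrics import CodingSequence
from .decay_fitting import DecaySeries

__all__ = [
    "rng_for",
    "gen_cds_with_planted_stability",
    "gen_decay_series",
    "gen_fish_dataset",
    "gen_qpcr_plate",
]

#: typical fission-yeast cell girth used for the background-spot box (µm);
#: a fixture convention, not a biological claim
CELL_GIRTH_UM = 3.5


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for one generator call."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# CDS with planted codon-stability relationship


def gen_cds_with_planted_stability(
    n_genes: int = 300,
    gene_length_codons: int = 300,
    stabilizing_codons: tuple[str, ...] = ("GCT", "GAA", "AAG", "TTC"),
    planted_r: float = 0.7,
    noise_sd: float | None = None,
    seed: int = 0,
    base_half_life: float = 30.0,
    half_life_span: float = 40.0,
    length_jitter: float = 0.3,
) -> tuple[list[CodingSequence], pd.Series]:
    """Genes whose stabilizing-codon content predicts mRNA half-life.

    Each gene's target content f of the stabilizing codon set is drawn
    from a spread Beta(2, 2) distribution and the gene body is sampled
    accordingly; the half-life is then an affine function of the gene's
    *realized* stabilizing-codon frequency plus Gaussian noise whose
    standard deviation is calibrated so that the population correlation
    between frequency and half-life equals ``planted_r`` (``noise_sd``
    overrides the calibration; 0 makes the relationship exactly
    collinear).  Genes carry a start codon, a stop codon and a length
    that is a multiple of 3; lengths vary uniformly within
    ``±length_jitter`` of the nominal length, as real gene lengths do
    (this also keeps every codon's frequency variable across genes, so
    no CSC is undefined).  The start codon itself is never planted, so
    its CSC is expected to sit near zero rather than below it.

    Returns ``(cds_list, half_life_series)`` (half-lives in minutes,
    indexed by gene_id).
    """
    if not 0.0 < planted_r < 1.0:
        raise ValueError("planted_r must lie in (0, 1)")
    stab = tuple(stabilizing_codons)
    for c in stab:
        if c not in SENSE_CODONS:
            raise ValueError(f"{c} is not a sense codon")
    others = tuple(c for c in SENSE_CODONS if c not in stab and c != START_CODON)
    rng = rng_for(seed, "cds_planted_stability")

    body_len = gene_length_codons - 2  # minus start and stop
    if body_len < 1:
        raise ValueError("gene_length_codons must be >= 3")

    f = rng.beta(2.0, 2.0, size=n_genes)  # spread of stabilizing-codon content
    cds_list: list[CodingSequence] = []
    genes = [f"synth{i:05d}" for i in range(n_genes)]
    lo = max(1, int(body_len * (1.0 - length_jitter)))
    hi = max(lo + 1, int(body_len * (1.0 + length_jitter)))
    body_lens = rng.integers(lo, hi + 1, size=n_genes)
    realized = np.empty(n_genes)
    for i, (gid, fi, bl) in enumerate(zip(genes, f, body_lens)):
        n_stab = rng.binomial(bl, fi)
        body = list(rng.choice(stab, size=n_stab)) + list(
            rng.choice(others, size=int(bl) - n_stab)
        )
        rng.shuffle(body)
        codons = (START_CODON, *body, "TAA")
        realized[i] = n_stab / (bl + 1)  # sense codons = start + body
        cds_list.append(
            CodingSequence(gene_id=gid, codons=codons, has_start=True, has_stop=True)
        )

    slope = half_life_span
    signal_sd = slope * realized.std()
    if noise_sd is None:
        noise_sd = signal_sd * math.sqrt(1.0 / planted_r**2 - 1.0)
    hl = (
        base_half_life
        + slope * (realized - realized.mean())
        + rng.normal(0.0, noise_sd, n_genes)
    )
    hl = np.maximum(hl, 0.5)  # positivity guard; rarely binds at the defaults
    half_lives = pd.Series(hl, index=genes, name="half_life_min")
    return cds_list, half_lives


def write_fasta(cds_list, path) -> None:
    """Deterministic FASTA writer (60-column wrap) for generated genes."""
    with open(path, "w") as fh:
        for cds in cds_list:
            fh.write(f">{cds.gene_id}\n")
            seq = cds.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# decay time courses


def gen_decay_series(
    true_hl_min: float = 8.0,
    mrna0: float = 0.9,
    timepoints: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0),
    n_replicates: int = 2,
    lognormal_sd: float = 0.1,
    genotype_effect_hl: float | None = None,
    replicate_sd: float = 0.0,
    gene: str = "geneA",
    genotypes: tuple[str, str] = ("wt", "mut"),
    seed: int = 0,
) -> list[DecaySeries]:
    """Exponential decay series with multiplicative noise and replicates.

    rel_expr = mrna0 * 2^(-t / HL) * exp(eps), eps ~ N(0, lognormal_sd²);
    the time-0 point, when present, is fixed at 1 (expression is
    measured relative to t=0, and non-instantaneous labeling leaves the
    t>0 curve with amplitude mrna0 < 1).  A second genotype with
    HL = true_hl + genotype_effect_hl is emitted whenever
    ``genotype_effect_hl`` is given (0 produces a two-genotype null);
    ``replicate_sd`` adds per-replicate lognormal jitter to both
    amplitude and decay rate (random intercepts and slopes).
    """
    rng = rng_for(seed, "decay_series")
    t = np.asarray(timepoints, dtype=float)
    out: list[DecaySeries] = []
    hls = {genotypes[0]: true_hl_min}
    if genotype_effect_hl is not None:
        hls[genotypes[1]] = true_hl_min + genotype_effect_hl
    for genotype, hl in hls.items():
        for rep in range(n_replicates):
            amp = mrna0 * math.exp(rng.normal(0.0, replicate_sd))
            rate = (math.log(2.0) / hl) * math.exp(rng.normal(0.0, replicate_sd))
            y = amp * np.exp(-rate * t) * np.exp(
                rng.normal(0.0, lognormal_sd, t.size)
            )
            y[t == 0] = 1.0
            out.append(
                DecaySeries(
                    gene=gene,
                    genotype=genotype,
                    replicate=f"rep{rep + 1}",
                    times=t.copy(),
                    rel_expr=y,
                )
            )
    return out


def decay_series_frame(series_list) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, y in zip(s.times, s.rel_expr):
            rows.append((s.gene, s.genotype, s.replicate, t, y))
    return pd.DataFrame(
        rows, columns=["gene", "genotype", "replicate", "time_min", "rel_expr"]
    )


# ---------------------------------------------------------------------------
# smFISH cells and spots


def gen_fish_dataset(
    n_cells: int = 200,
    length_lognormal_params: tuple[float, float] = (2.2, 0.25),
    b0: float = 1.25,
    b_length: float = 1.0,
    genotype_log_ratio: float = 0.0,
    coloc_fraction: float = 0.8,
    jitter_sd_um: float = 0.1,
    background_spots_per_cell: float = 1.0,
    genotypes: tuple[str, str] = ("wt", "alt"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell count table and per-spot 3D coordinate table.

    Counts follow a Poisson log-link model on centered log cell length
    (lengths are lognormal, in µm):
    counts ~ Poisson(exp(b0 + b_length * cll + genotype_log_ratio * g)).
    Spots for channel A are placed uniformly in a cell-shaped box
    (length x 3.5 x 3.5 µm); a fraction ``coloc_fraction`` of them get a
    channel-B partner offset by isotropic Gaussian jitter, and channel B
    additionally receives Poisson(``background_spots_per_cell``) spots
    uniform in the box.  When ``genotype_log_ratio`` is 0 a single
    genotype is generated.

    Returns ``(cells, spots)`` DataFrames matching the fish_stats input
    schema (cells: cell_id, image_id, replicate_id, genotype, length,
    count_whole, count_cyto, count_nuc; spots: cell_id, channel, x, y,
    z, intensity).
    """
    rng = rng_for(seed, "fish_dataset")
    mu_l, sd_l = length_lognormal_params
    genos = list(genotypes) if genotype_log_ratio != 0.0 else [genotypes[0]]

    cell_rows = []
    spot_rows = []
    cid = 0
    for gi, geno in enumerate(genos):
        lengths = rng.lognormal(mu_l, sd_l, n_cells)
        cll = np.log(lengths) - np.log(lengths).mean()
        lam = np.exp(b0 + b_length * cll + genotype_log_ratio * gi)
        counts = rng.poisson(lam)
        for L, c in zip(lengths, counts):
            cell_id = f"cell{cid:05d}"
            cid += 1
            c_nuc = rng.binomial(c, 0.2)
            cell_rows.append(
                (cell_id, f"img{cid % 10}", "rep1", geno, float(L),
                 int(c), int(c - c_nuc), int(c_nuc))
            )
            # channel A spots uniform in the cell box
            n_a = int(c)
            xyz = np.column_stack(
                [
                    rng.uniform(0.0, L, n_a),
                    rng.uniform(0.0, CELL_GIRTH_UM, n_a),
                    rng.uniform(0.0, CELL_GIRTH_UM, n_a),
                ]
            )
            inten_a = rng.lognormal(0.0, 0.3, n_a)
            for j in range(n_a):
                spot_rows.append((cell_id, "a", *xyz[j], inten_a[j]))
            paired = rng.random(n_a) < coloc_fraction
            partners = xyz[paired] + rng.normal(0.0, jitter_sd_um,
                                                (int(paired.sum()), 3))
            inten_b = rng.lognormal(0.0, 0.3, partners.shape[0])
            for j in range(partners.shape[0]):
                spot_rows.append((cell_id, "b", *partners[j], inten_b[j]))
            n_bg = rng.poisson(background_spots_per_cell)
            bg = np.column_stack(
                [
                    rng.uniform(0.0, L, n_bg),
                    rng.uniform(0.0, CELL_GIRTH_UM, n_bg),
                    rng.uniform(0.0, CELL_GIRTH_UM, n_bg),
                ]
            )
            inten_bg = rng.lognormal(0.0, 0.3, n_bg)
            for j in range(n_bg):
                spot_rows.append((cell_id, "b", *bg[j], inten_bg[j]))

    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "image_id", "replicate_id", "genotype", "length",
                 "count_whole", "count_cyto", "count_nuc"],
    )
    spots = pd.DataFrame(
        spot_rows, columns=["cell_id", "channel", "x", "y", "z", "intensity"]
    )
    return cells, spots


# ---------------------------------------------------------------------------
# qPCR plates


def gen_qpcr_plate(
    true_ratios: dict[str, float] | None = None,
    efficiencies: dict[str, float] | None = None,
    reference_targets: tuple[str, ...] = ("ref1", "ref2"),
    ct_noise_sd: float = 0.0,
    control_ct: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table consistent with the efficiency-corrected ratio model.

    For each target with true expression ratio R (sample vs control) and
    efficiency E, Ct_sample = Ct_control - log(R)/log(1+E); reference
    targets have ratio 1.  Running the relative-expression formula on
    the emitted table recovers ``true_ratios`` exactly as
    ``ct_noise_sd`` goes to 0.

    Returns a long DataFrame: sample_id, target, ct, efficiency, role.
    """
    if true_ratios is None:
        true_ratios = {"geneA": 2.0}
    if efficiencies is None:
        efficiencies = {t: 1.0 for t in list(true_ratios) + list(reference_targets)}
    rng = rng_for(seed, "qpcr_plate")
    rows = []
    for target, ratio in true_ratios.items():
        eff = efficiencies.get(target, 1.0)
        ct_s = control_ct - math.log(ratio) / math.log(1.0 + eff)
        rows.append(("control", target, control_ct + rng.normal(0, ct_noise_sd),
                     eff, "target"))
        rows.append(("sample", target, ct_s + rng.normal(0, ct_noise_sd),
                     eff, "target"))
    for target in reference_targets:
        eff = efficiencies.get(target, 1.0)
        rows.append(("control", target, control_ct + rng.normal(0, ct_noise_sd),
                     eff, "reference"))
        rows.append(("sample", target, control_ct + rng.normal(0, ct_noise_sd),
                     eff, "reference"))
    return pd.DataFrame(
        rows, columns=["sample_id", "target", "ct", "efficiency", "role"]
    )
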