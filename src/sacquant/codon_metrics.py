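"""Codon-usage and codon-stability metrics.

The codon stabilization coefficient (CSC) of a codon is the Pearson
correlation, across genes, between the codon's within-gene frequency of
occurrence and the gene's mRNA half-life.  Gene-level summaries are the
arithmetic mean CSC over codon occurrences (CSC_g), the geometric-mean
tRNA adaptation index (tAI_g), and the percentage of optimal codons.
A sliding-window CSC profile with a codon-order permutation null locates
clusters of stabilizing or destabilizing codons within a gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codons import SENSE_CODONS, STOP_CODONS, START_CODON, is_valid_codon

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "CSCTable",
    "GeneMetrics",
    "CodonProfile",
    "load_cds",
    "codon_frequencies",
    "frequency_matrix",
    "harmonize_half_lives",
    "compute_csc",
    "csc_g",
    "tai_g",
    "percent_optimal",
    "gene_metrics",
    "moving_average_profile",
    "permutation_null",
]


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding sequence decomposed into codons.

    ``codons`` includes the stop codon when present; metric functions
    exclude it.
    """

    gene_id: str
    codons: tuple[str, ...]
    has_start: bool
    has_stop: bool

    @classmethod
    def from_sequence(cls, gene_id: str, seq: str) -> "CodingSequence":
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"{gene_id}: length {len(seq)} not a multiple of 3")
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        if not codons:
            raise ValueError(f"{gene_id}: empty sequence")
        for c in codons:
            if not is_valid_codon(c):
                raise ValueError(f"{gene_id}: ambiguous or invalid codon {c!r}")
        return cls(
            gene_id=gene_id,
            codons=codons,
            has_start=codons[0] == START_CODON,
            has_stop=codons[-1] in STOP_CODONS,
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Codons excluding a terminal stop (internal stops are kept)."""
        if self.has_stop:
            return self.codons[:-1]
        return self.codons

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    def __len__(self) -> int:
        return len(self.codons)


@dataclass
class CSCTable:
    """Per-codon stabilization coefficients.

    ``values`` is indexed by the 61 sense codons; codons whose frequency
    had zero variance across genes are NaN (undefined), never 0.
    """

    values: pd.Series
    n_genes_used: int
    source: str = ""

    def __post_init__(self) -> None:
        self.values = self.values.reindex(list(SENSE_CODONS))
        defined = self.values.dropna()
        if len(defined) and not ((defined >= -1 - 1e-12) & (defined <= 1 + 1e-12)).all():
            raise ValueError("CSC values must lie in [-1, 1]")

    def __getitem__(self, codon: str) -> float:
        return float(self.values[codon])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": self.values.index, "csc": self.values.values,
             "n_genes": self.n_genes_used}
        )


@dataclass(frozen=True)
class GeneMetrics:
    gene_id: str
    csc_g: float
    tai_g: float | None
    pct_optimal: float | None
    n_codons: int
    n_skipped: int = 0  # codon occurrences without a defined CSC


@dataclass
class CodonProfile:
    """Moving-average CSC profile with its codon-permutation null."""

    gene_id: str
    window: int
    positions: np.ndarray  # 1-based codon coordinate of each window center
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    flags: np.ndarray  # strings: 'below' | 'within' | 'above'
    n_perm: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "flag": self.flags,
            }
        )


# ---------------------------------------------------------------------------
# loading and frequencies


def load_cds(
    fasta_path,
    require_start: bool = True,
    require_stop: bool = True,
    return_report: bool = False,
):
    """Read coding sequences from a FASTA file, applying QC filters.

    Sequences are excluded (with a logged reason) when their length is
    not a multiple of 3, when they contain ambiguous nucleotides, or when
    they lack a start/stop codon and the corresponding filter is on.
    """
    records: list[CodingSequence] = []
    report: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("%s: empty record, skipped", rec.id)
            report[rec.id] = "empty record"
            continue
        if len(seq) % 3 != 0:
            logger.warning("%s: length not multiple of 3, excluded", rec.id)
            report[rec.id] = "length not multiple of 3"
            continue
        try:
            cds = CodingSequence.from_sequence(rec.id, seq)
        except ValueError as exc:
            logger.warning("%s: %s, excluded", rec.id, exc)
            report[rec.id] = "ambiguous or invalid nucleotides"
            continue
        if require_start and not cds.has_start:
            logger.warning("%s: lacks start codon, excluded", rec.id)
            report[rec.id] = "lacks start codon"
            continue
        if require_stop and not cds.has_stop:
            logger.warning("%s: lacks stop codon, excluded", rec.id)
            report[rec.id] = "lacks stop codon"
            continue
        records.append(cds)
    if return_report:
        return records, report
    return records


def codon_frequencies(cds: CodingSequence, counts: bool = False) -> pd.Series:
    """Within-gene codon usage over the 61 sense codons.

    Returns proportions summing to 1 (or raw counts with ``counts=True``);
    the stop codon is excluded from numerator and denominator.
    """
    sense = cds.sense_codons
    if not sense:
        raise ValueError(f"{cds.gene_id}: no sense codons")
    vec = pd.Series(0.0, index=list(SENSE_CODONS))
    for c in sense:
        if c in STOP_CODONS:
            # internal stop: counted nowhere, like the terminal stop
            continue
        vec[c] += 1.0
    total = vec.sum()
    if total == 0:
        raise ValueError(f"{cds.gene_id}: no sense codons")
    if counts:
        return vec
    return vec / total


def frequency_matrix(cds_list: Iterable[CodingSequence], counts: bool = False) -> pd.DataFrame:
    """Genes x 61 sense codons frequency matrix."""
    rows = {cds.gene_id: codon_frequencies(cds, counts=counts) for cds in cds_list}
    return pd.DataFrame.from_dict(rows, orient="index")[list(SENSE_CODONS)]


# ---------------------------------------------------------------------------
# half-life harmonization and CSC


def harmonize_half_lives(
    table_a: pd.Series,
    table_b: pd.Series,
    iqr_mult: float = 10.0,
    rank_dev: float = 2500.0,
    outlier_table: str = "a",
    quantile_method: str = "linear",
):
    """Remove outlier genes before correlating codon usage with half-life.

    Two rules: (i) genes whose half-life in the designated table exceeds
    Q3 + ``iqr_mult``·IQR; (ii) genes whose rank position differs by more
    than ``rank_dev`` between the two datasets (average ranks for ties,
    applied to genes present in both).  Removed genes are dropped from
    both tables.

    Returns ``(filtered_a, filtered_b, removed_report)`` where the report
    is a DataFrame with columns gene_id and rule.
    """
    if outlier_table not in ("a", "b"):
        raise ValueError("outlier_table must be 'a' or 'b'")
    a = table_a.dropna().astype(float)
    b = table_b.dropna().astype(float)
    removed: list[tuple[str, str]] = []

    designated = a if outlier_table == "a" else b
    if len(designated):
        q1, q3 = np.quantile(designated.values, [0.25, 0.75], method=quantile_method)
        upper = q3 + iqr_mult * (q3 - q1)
        for g in designated.index[designated.values > upper]:
            removed.append((g, "iqr"))

    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        logger.warning("no shared genes between tables; rank-deviation rule skipped")
    else:
        from scipy.stats import rankdata

        ra = pd.Series(rankdata(a.loc[shared].values), index=shared)
        rb = pd.Series(rankdata(b.loc[shared].values), index=shared)
        dev = (ra - rb).abs()
        for g in dev.index[dev > rank_dev]:
            removed.append((g, "rank"))

    report = pd.DataFrame(removed, columns=["gene_id", "rule"]).drop_duplicates("gene_id")
    drop = set(report["gene_id"])
    return a.drop(index=drop, errors="ignore"), b.drop(index=drop, errors="ignore"), report


def compute_csc(
    freq_matrix: pd.DataFrame,
    half_lives: pd.Series,
    log_half_life: bool = False,
    source: str = "",
) -> CSCTable:
    """Per-codon Pearson correlation between codon frequency and half-life.

    The correlation runs across the genes shared between the frequency
    matrix and the half-life table.  Half-lives are used on their natural
    scale by default (``log_half_life=True`` correlates against
    log half-life instead).  Codons whose frequency has zero variance
    across the shared genes get an undefined (NaN) CSC.
    """
    hl = half_lives.dropna().astype(float)
    shared = freq_matrix.index.intersection(hl.index)
    n = len(shared)
    if n < 3:
        raise ValueError(f"insufficient genes: {n} shared, need >= 3")
    F = freq_matrix.loc[shared, list(SENSE_CODONS)].to_numpy(dtype=float)
    y = hl.loc[shared].to_numpy(dtype=float)
    if log_half_life:
        y = np.log(y)

    yc = y - y.mean()
    Fc = F - F.mean(axis=0)
    sy = math.sqrt(float(yc @ yc))
    sf = np.sqrt((Fc * Fc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Fc.T @ yc) / (sf * sy)
    r[sf == 0] = np.nan
    if sy == 0:
        r[:] = np.nan
    values = pd.Series(np.clip(r, -1.0, 1.0), index=list(SENSE_CODONS))
    values[sf == 0] = np.nan
    return CSCTable(values=values, n_genes_used=n, source=source)


# ---------------------------------------------------------------------------
# gene-level metrics


def _scorable_values(cds: CodingSequence, csc_table: CSCTable) -> tuple[np.ndarray, int]:
    vals = []
    skipped = 0
    for c in cds.sense_codons:
        if c in STOP_CODONS:
            skipped += 1
            continue
        v = csc_table.values.get(c, np.nan)
        if np.isnan(v):
            skipped += 1
        else:
            vals.append(float(v))
    return np.asarray(vals, dtype=float), skipped


def csc_g(cds: CodingSequence, csc_table: CSCTable) -> float:
    """Gene-level CSC: arithmetic mean of per-occurrence CSC values.

    Repeated codons contribute each time they occur; the stop codon and
    any codon without a defined CSC are excluded from both numerator and
    denominator.
    """
    vals, skipped = _scorable_values(cds, csc_table)
    if vals.size == 0:
        raise ValueError(f"{cds.gene_id}: no scorable codons")
    if skipped:
        logger.info("%s: %d codon occurrences without defined CSC skipped",
                    cds.gene_id, skipped)
    return float(vals.mean())


def tai_g(cds: CodingSequence, tai_weights: Mapping[str, float]) -> float:
    """Gene-level tAI: geometric mean of per-occurrence tAI weights (stop excluded)."""
    ws = []
    for c in cds.sense_codons:
        if c in STOP_CODONS:
            continue
        w = float(tai_weights[c])
        if w < 0:
            raise ValueError(f"negative tAI weight for {c}")
        ws.append(w)
    if not ws:
        raise ValueError(f"{cds.gene_id}: no scorable codons")
    ws_arr = np.asarray(ws)
    if (ws_arr == 0).any():
        logger.warning("%s: zero tAI weight encountered; tai_g = 0", cds.gene_id)
        return 0.0
    return float(np.exp(np.mean(np.log(ws_arr))))


def percent_optimal(cds: CodingSequence, optimal_codons: Iterable[str]) -> float:
    """Percentage of sense-codon occurrences drawn from the optimal set."""
    optimal = set(optimal_codons)
    sense = [c for c in cds.sense_codons if c not in STOP_CODONS]
    if not sense:
        raise ValueError(f"{cds.gene_id}: no sense codons")
    n_opt = sum(1 for c in sense if c in optimal)
    return 100.0 * n_opt / len(sense)


def gene_metrics(
    cds: CodingSequence,
    csc_table: CSCTable,
    tai_weights: Mapping[str, float] | None = None,
    optimal_codons: Iterable[str] | None = None,
) -> GeneMetrics:
    vals, skipped = _scorable_values(cds, csc_table)
    if vals.size == 0:
        raise ValueError(f"{cds.gene_id}: no scorable codons")
    return GeneMetrics(
        gene_id=cds.gene_id,
        csc_g=float(vals.mean()),
        tai_g=tai_g(cds, tai_weights) if tai_weights is not None else None,
        pct_optimal=(
            percent_optimal(cds, optimal_codons) if optimal_codons is not None else None
        ),
        n_codons=len([c for c in cds.sense_codons if c not in STOP_CODONS]),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# sliding-window profile and permutation null


def _per_codon_csc(cds: CodingSequence, csc_table: CSCTable) -> np.ndarray:
    vals = np.array(
        [csc_table.values.get(c, np.nan) for c in cds.sense_codons], dtype=float
    )
    if np.isnan(vals).any():
        raise ValueError(
            f"{cds.gene_id}: codons without a defined CSC in profile; "
            "filter the gene or supply a complete CSC table"
        )
    return vals


def _moving_average(vals: np.ndarray, window: int) -> np.ndarray:
    cs = np.concatenate(([0.0], np.cumsum(vals)))
    return (cs[window:] - cs[:-window]) / window


def moving_average_profile(
    cds: CodingSequence, csc_table: CSCTable, window: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average of per-codon CSC along the gene.

    Returns ``(positions, observed)``: 1-based codon coordinates of the
    window centers and the averaged values.  Positions without a full
    window are omitted.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    vals = _per_codon_csc(cds, csc_table)
    n = vals.size
    if n < window:
        raise ValueError(f"{cds.gene_id}: {n} codons shorter than window {window}")
    observed = _moving_average(vals, window)
    half = (window - 1) // 2
    positions = np.arange(half + 1, n - half + 1)
    return positions, observed


def permutation_null(
    cds: CodingSequence,
    csc_table: CSCTable,
    window: int = 9,
    n_perm: int = 10000,
    seed: int | None = None,
    sd_mult: float = 2.0,
) -> CodonProfile:
    """Sliding-window CSC profile against a codon-order permutation null.

    The within-gene codon order is randomized ``n_perm`` times (the
    multiset of CSC values is preserved); window positions where the
    observed moving average deviates from the null mean by more than
    ``sd_mult`` null standard deviations are flagged 'above' or 'below'.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    positions, observed = moving_average_profile(cds, csc_table, window)
    vals = _per_codon_csc(cds, csc_table)
    rng = np.random.default_rng(seed)

    # shuffle rows of a tiled value matrix, then moving-average each row
    perm = np.tile(vals, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    cs = np.concatenate(
        (np.zeros((n_perm, 1)), np.cumsum(perm, axis=1)), axis=1
    )
    ma = (cs[:, window:] - cs[:, :-window]) / window
    null_mean = ma.mean(axis=0)
    null_sd = ma.std(axis=0, ddof=0)

    dev = observed - null_mean
    flags = np.where(
        dev > sd_mult * null_sd,
        "above",
        np.where(dev < -sd_mult * null_sd, "below", "within"),
    )
    return CodonProfile(
        gene_id=cds.gene_id,
        window=window,
        positions=positions,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        flags=flags,
        n_perm=n_perm,
        seed=seed,
    )
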