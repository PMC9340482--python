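"""Codon frequency, CSC, gene metrics and sliding-window profile tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr

from sacquant.codon_metrics import (
    CodingSequence,
    CSCTable,
    codon_frequencies,
    compute_csc,
    csc_g,
    frequency_matrix,
    gene_metrics,
    harmonize_half_lives,
    load_cds,
    moving_average_profile,
    percent_optimal,
    permutation_null,
    tai_g,
)
from sacquant.codons import SENSE_CODONS


# ---------------------------------------------------------------------------
# loading and decomposition


class TestLoadCds:
    def test_decomposition_and_flags(self, tmp_path):
        fa = tmp_path / "in.fasta"
        fa.write_text(">g1\nATGAAATAA\n")
        (recs,) = (load_cds(fa),)
        assert len(recs) == 1
        cds = recs[0]
        assert cds.codons == ("ATG", "AAA", "TAA")
        assert cds.has_start and cds.has_stop
        assert cds.sequence == "ATGAAATAA"

    @pytest.mark.parametrize(
        "seq,reason",
        [
            ("ATGAAAA", "length not multiple of 3"),
            ("TTGAAATAA", "lacks start codon"),
            ("ATGAANTAA", "ambiguous or invalid nucleotides"),
            ("ATGAAAGGG", "lacks stop codon"),
        ],
    )
    def test_exclusions_logged(self, tmp_path, seq, reason):
        fa = tmp_path / "in.fasta"
        fa.write_text(f">good\nATGAAATAA\n>bad\n{seq}\n")
        recs, report = load_cds(fa, return_report=True)
        assert [c.gene_id for c in recs] == ["good"]
        assert report["bad"] == reason

    def test_start_stop_filter_off(self, tmp_path):
        fa = tmp_path / "in.fasta"
        fa.write_text(">g\nTTGAAAGGG\n")
        recs = load_cds(fa, require_start=False, require_stop=False)
        assert len(recs) == 1 and not recs[0].has_start and not recs[0].has_stop

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_cds(tmp_path / "missing.fasta")


class TestCodonFrequencies:
    def test_two_sense_codons(self, make_cds):
        freqs = codon_frequencies(make_cds("g1", "ATGAAATAA"))
        assert freqs["ATG"] == 0.5 and freqs["AAA"] == 0.5
        assert freqs.drop(["ATG", "AAA"]).eq(0).all()

    def test_repeated_codon(self, make_cds):
        freqs = codon_frequencies(make_cds("g2", "ATGGCTGCTTAA"))
        assert freqs["ATG"] == pytest.approx(1 / 3)
        assert freqs["GCT"] == pytest.approx(2 / 3)

    def test_normalization(self, make_cds):
        freqs = codon_frequencies(make_cds("g3", "ATG" + "GAAAAGTTC" * 7 + "TGA"))
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stop_only_gene_errors(self):
        cds = CodingSequence(gene_id="s", codons=("TAA",), has_start=False,
                             has_stop=True)
        with pytest.raises(ValueError, match="no sense codons"):
            codon_frequencies(cds)


# ---------------------------------------------------------------------------
# outlier harmonization


class TestHarmonize:
    def test_iqr_rule_matches_hand_computation(self):
        vals = [1.0, 2.0, 3.0, 4.0, 1000.0]
        a = pd.Series(vals, index=[f"g{i}" for i in range(5)])
        b = a.copy()
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # independent oracle
        upper = q3 + 10 * (q3 - q1)
        fa, fb, report = harmonize_half_lives(a, b)
        expected_removed = {g for g, v in a.items() if v > upper}
        assert set(report.loc[report["rule"] == "iqr", "gene_id"]) == expected_removed
        assert expected_removed == {"g4"}  # 1000 > 4 + 10*2
        assert "g4" not in fa.index and "g4" not in fb.index

    def test_identical_rankings_remove_nothing(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        b = a * 7.0
        _, _, report = harmonize_half_lives(a, b, iqr_mult=100)
        assert report.empty

    def test_rank_dev_zero_boundary(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([3.0, 2.0, 1.0], index=list("abc"))  # a and c swap ranks
        fa, fb, report = harmonize_half_lives(a, b, rank_dev=0, iqr_mult=100)
        assert set(report["gene_id"]) == {"a", "c"}

    def test_empty_intersection_skips_rank_rule(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
        fa, fb, report = harmonize_half_lives(a, b, iqr_mult=100)
        assert report.empty and len(fa) == 3 and len(fb) == 3

    def test_outlier_rule_on_designated_table(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        b = pd.Series([1.0, 2.0, 3.0, 4.0, 1000.0], index=list("abcde"))
        _, _, rep_a = harmonize_half_lives(a, b, outlier_table="a", rank_dev=10)
        _, _, rep_b = harmonize_half_lives(a, b, outlier_table="b", rank_dev=10)
        assert rep_a.empty
        assert set(rep_b["gene_id"]) == {"e"}


# ---------------------------------------------------------------------------
# CSC computation


class TestComputeCsc:
    def test_matches_scipy_pearson(self):
        # GCT frequencies [2/3, 1/3, 0] against half-lives [10, 5, 2]
        F = pd.DataFrame(0.0, index=["g1", "g2", "g3"], columns=list(SENSE_CODONS))
        F.loc[:, "GCT"] = [2 / 3, 1 / 3, 0.0]
        F.loc[:, "AAA"] = 1.0 - F["GCT"]
        hl = pd.Series([10.0, 5.0, 2.0], index=["g1", "g2", "g3"])
        table = compute_csc(F, hl)
        expected = pearsonr(F["GCT"], hl).statistic  # independent oracle
        assert table["GCT"] == pytest.approx(expected, abs=1e-12)
        assert table["GCT"] == pytest.approx(0.990, abs=5e-4)
        assert table["AAA"] == pytest.approx(-expected, abs=1e-12)

    def test_collinear_gives_one(self):
        hl = pd.Series([2.0, 4.0, 8.0, 16.0], index=list("abcd"))
        F = pd.DataFrame(0.0, index=list("abcd"), columns=list(SENSE_CODONS))
        F["GGT"] = hl.values / 32.0
        F["TTA"] = 1.0 - F["GGT"]
        table = compute_csc(F, hl)
        assert table["GGT"] == pytest.approx(1.0, abs=1e-12)
        assert table["TTA"] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_codon_is_undefined(self):
        F = pd.DataFrame(0.0, index=list("abc"), columns=list(SENSE_CODONS))
        F["ATG"] = 0.5  # identical in every gene
        F["AAA"] = [0.5, 0.3, 0.2]
        F["CCC"] = 1.0 - F["ATG"] - F["AAA"]
        table = compute_csc(F, pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert np.isnan(table["ATG"])
        assert not np.isnan(table["AAA"])

    def test_insufficient_genes(self):
        F = pd.DataFrame(0.5, index=["a", "b"], columns=list(SENSE_CODONS))
        with pytest.raises(ValueError, match="insufficient genes"):
            compute_csc(F, pd.Series([1.0, 2.0], index=["a", "b"]))

    def test_permuted_half_lives_center_at_zero(self):
        rng = np.random.default_rng(7)
        n, B = 60, 200
        F = pd.DataFrame(
            rng.dirichlet(np.ones(len(SENSE_CODONS)), size=n),
            index=[f"g{i}" for i in range(n)],
            columns=list(SENSE_CODONS),
        )
        hl = pd.Series(rng.uniform(2, 60, n), index=F.index)
        means = np.zeros(len(SENSE_CODONS))
        for _ in range(B):
            perm = pd.Series(rng.permutation(hl.values), index=hl.index)
            means += compute_csc(F, perm).values.values
        means /= B
        # permutation null keeps every mean CSC within ~3/sqrt(B) of zero
        assert np.nanmax(np.abs(means)) < 3.0 / np.sqrt(B)

    def test_values_bounded(self):
        rng = np.random.default_rng(3)
        F = pd.DataFrame(
            rng.dirichlet(np.ones(len(SENSE_CODONS)), size=30),
            index=[f"g{i}" for i in range(30)],
            columns=list(SENSE_CODONS),
        )
        table = compute_csc(F, pd.Series(rng.uniform(1, 50, 30), index=F.index))
        defined = table.values.dropna()
        assert ((defined >= -1) & (defined <= 1)).all()


# ---------------------------------------------------------------------------
# gene-level metrics


class TestGeneMetrics:
    def test_csc_g_examples(self, make_cds):
        table = CSCTable(
            values=pd.Series({"ATG": 0.2, "AAA": -0.4}), n_genes_used=10
        )
        assert csc_g(make_cds("g", "ATGAAATAA"), table) == pytest.approx(-0.1)

    def test_csc_g_occurrence_weighting(self, make_cds):
        table = CSCTable(
            values=pd.Series({"ATG": 0.1, "GCT": 0.1, "TTA": -0.3}),
            n_genes_used=10,
        )
        # codons ATG GCT GCT TTA: mean(0.1, 0.1, 0.1, -0.3) = 0.0
        assert csc_g(make_cds("g", "ATGGCTGCTTTATAA"), table) == pytest.approx(0.0)

    def test_csc_g_single_codon(self, make_cds):
        table = CSCTable(values=pd.Series({"GGT": 0.37}), n_genes_used=10)
        cds = CodingSequence("g", ("GGT", "GGT", "GGT"), False, False)
        assert csc_g(cds, table) == pytest.approx(0.37)

    def test_csc_g_skips_undefined(self, make_cds):
        table = CSCTable(
            values=pd.Series({"ATG": np.nan, "AAA": 0.4}), n_genes_used=10
        )
        cds = make_cds("g", "ATGAAATAA")
        assert csc_g(cds, table) == pytest.approx(0.4)
        gm = gene_metrics(cds, table)
        assert gm.n_skipped == 1

    def test_csc_g_concatenation_is_weighted_mean(self, toy_csc_table, make_cds):
        a = make_cds("a", "ATGGCTGAAAAG")
        b = make_cds("b", "ATGTTCTTATCTCGT")
        combined = CodingSequence(
            "ab", a.codons + b.codons, has_start=True, has_stop=False
        )
        na, nb = len(a.codons), len(b.codons)
        expected = (
            na * csc_g(a, toy_csc_table) + nb * csc_g(b, toy_csc_table)
        ) / (na + nb)
        assert csc_g(combined, toy_csc_table) == pytest.approx(expected, abs=1e-12)

    def test_tai_g_examples(self):
        cds = CodingSequence("g", ("GCT", "GCC"), False, False)
        assert tai_g(cds, {"GCT": 0.25, "GCC": 0.04}) == pytest.approx(0.1)
        assert tai_g(cds, {"GCT": 0.5, "GCC": 0.5}) == pytest.approx(0.5)

    def test_tai_g_zero_weight(self):
        cds = CodingSequence("g", ("GCT", "GCC"), False, False)
        assert tai_g(cds, {"GCT": 0.0, "GCC": 0.5}) == 0.0

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_tai_g_at_most_arithmetic_mean(self, weights):
        codons = tuple(SENSE_CODONS[i % len(SENSE_CODONS)] for i in range(len(weights)))
        # repeated codons must share a weight: index weights by codon
        wmap = {}
        for c, w in zip(codons, weights):
            wmap.setdefault(c, w)
        used = [wmap[c] for c in codons]
        cds = CodingSequence("g", codons, False, False)
        assert tai_g(cds, wmap) <= np.mean(used) + 1e-12

    def test_percent_optimal(self, make_cds):
        cds = make_cds("g", "ATGGCTTTATAA")  # sense: ATG GCT TTA
        assert percent_optimal(cds, {"ATG", "GCT"}) == pytest.approx(66.67, abs=0.01)
        assert percent_optimal(cds, set(SENSE_CODONS)) == 100.0
        assert percent_optimal(cds, set()) == 0.0


# ---------------------------------------------------------------------------
# moving average and permutation null


class TestProfile:
    def test_constant_profile(self):
        table = CSCTable(values=pd.Series({"GGT": 0.3}), n_genes_used=5)
        cds = CodingSequence("g", ("GGT",) * 20, False, False)
        pos, obs = moving_average_profile(cds, table, window=9)
        assert np.allclose(obs, 0.3)
        assert len(obs) == 20 - 9 + 1
        assert pos[0] == 5 and pos[-1] == 16  # centered, 1-based

    def test_window_one_recovers_per_codon_values(self, toy_csc_table, make_cds):
        cds = make_cds("g", "ATGGCTGAAAAGTTCTAA")
        _, obs = moving_average_profile(cds, toy_csc_table, window=1)
        expected = [toy_csc_table[c] for c in cds.sense_codons]
        assert np.allclose(obs, expected)

    def test_full_window_equals_csc_g(self, toy_csc_table, make_cds):
        cds = make_cds("g", "ATGGCTGAAAAGTTCTCTCGTTAA")
        n = len(cds.sense_codons)
        if n % 2 == 0:
            cds = CodingSequence("g", cds.sense_codons[:-1], True, False)
            n -= 1
        _, obs = moving_average_profile(cds, toy_csc_table, window=n)
        assert len(obs) == 1
        assert obs[0] == pytest.approx(csc_g(cds, toy_csc_table))

    def test_gene_shorter_than_window_errors(self, toy_csc_table, make_cds):
        with pytest.raises(ValueError, match="shorter than window"):
            moving_average_profile(make_cds("g", "ATGAAATAA"), toy_csc_table, 9)

    def test_identical_codons_never_flagged(self):
        table = CSCTable(values=pd.Series({"GGT": 0.3}), n_genes_used=5)
        cds = CodingSequence("g", ("GGT",) * 30, False, False)
        prof = permutation_null(cds, table, window=9, n_perm=50, seed=0)
        assert np.allclose(prof.null_sd, 0.0)
        assert (prof.flags == "within").all()

    def test_flags_match_definition(self, toy_csc_table, make_cds):
        cds = make_cds("g", "ATG" + "GCTGAAAAGTTCTCTCGT" * 3 + "TAA")
        prof = permutation_null(cds, toy_csc_table, window=9, n_perm=300, seed=1)
        dev = prof.observed - prof.null_mean
        expect_above = dev > 2 * prof.null_sd
        expect_below = dev < -2 * prof.null_sd
        assert ((prof.flags == "above") == expect_above).all()
        assert ((prof.flags == "below") == expect_below).all()

    def test_seed_reproducibility(self, toy_csc_table, make_cds):
        cds = make_cds("g", "ATG" + "GCTGAAAAGTTCTCTCGT" * 3 + "TAA")
        p1 = permutation_null(cds, toy_csc_table, window=9, n_perm=200, seed=42)
        p2 = permutation_null(cds, toy_csc_table, window=9, n_perm=200, seed=42)
        assert np.array_equal(p1.null_mean, p2.null_mean)
        assert np.array_equal(p1.null_sd, p2.null_sd)

    def test_flags_invariant_under_csc_value_relabeling(self, make_cds):
        # two codon alphabets sharing the same CSC multiset give identical flags
        t1 = CSCTable(values=pd.Series({"GCT": 0.4, "TTA": -0.4}), n_genes_used=5)
        t2 = CSCTable(values=pd.Series({"CCA": 0.4, "GGA": -0.4}), n_genes_used=5)
        pattern = [0, 0, 0, 1, 1, 1, 0, 1, 0, 1, 1, 0, 0, 0, 1, 1]
        c1 = CodingSequence("g", tuple("GCT" if b else "TTA" for b in pattern),
                            False, False)
        c2 = CodingSequence("g", tuple("CCA" if b else "GGA" for b in pattern),
                            False, False)
        p1 = permutation_null(c1, t1, window=5, n_perm=400, seed=9)
        p2 = permutation_null(c2, t2, window=5, n_perm=400, seed=9)
        assert (p1.flags == p2.flags).all()

    def test_null_mean_matches_larger_permutation_sample(self, make_cds):
        # 12-codon gene: n_perm=2,000 null mean within Monte-Carlo error of
        # a 40,000-permutation estimate of the same quantity
        table = CSCTable(
            values=pd.Series({"GCT": 0.5, "TTA": -0.2, "CCA": 0.1}),
            n_genes_used=5,
        )
        cds = CodingSequence(
            "g", ("GCT", "TTA", "CCA", "GCT", "GCT", "TTA", "CCA", "CCA",
                  "TTA", "GCT", "TTA", "CCA"), False, False)
        small = permutation_null(cds, table, window=5, n_perm=2000, seed=0)
        big = permutation_null(cds, table, window=5, n_perm=40000, seed=1)
        mc_err = 4 * small.null_sd.max() / np.sqrt(2000)
        assert np.abs(small.null_mean - big.null_mean).max() < mc_err

    def test_frequency_matrix_shape(self, make_cds):
        genes = [make_cds("a", "ATGGCTTAA"), make_cds("b", "ATGAAATAA")]
        F = frequency_matrix(genes)
        assert F.shape == (2, 61)
        assert np.allclose(F.sum(axis=1), 1.0)
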