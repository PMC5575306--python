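import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medipdiff import (
    Gene,
    GenomicInterval,
    cgi_profile,
    count_in_windows,
    coupling,
    dedup,
    make_windows,
    metagene_profile,
    saturation,
    size_factors,
    subtelomeric_test,
)

from oracles import median_of_ratios, two_sample_t


class TestMakeWindows:
    def test_partial_final_window_kept(self):
        grid = make_windows({"c": 2500}, 1000)
        df = grid.to_frame()
        assert list(zip(df["start"], df["end"])) == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_single_window_chromosome(self):
        grid = make_windows({"c": 1000}, 1000)
        assert grid.n_windows == 1

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 0}, 1000)

    @settings(derandomize=True, max_examples=50)
    @given(L=st.integers(min_value=1, max_value=10_000_000))
    def test_window_lengths_sum_to_chromosome_length(self, L):
        grid = make_windows({"c": L}, 1000)
        assert int(grid.window_lengths().sum()) == L

    def test_sex_chromosome_exclusion(self):
        grid = make_windows({"chr1": 5000, "chrX": 5000, "Y": 5000}, 1000,
                            exclude_sex_chroms=True)
        assert grid.chroms == ["chr1"]


class TestDedup:
    def test_identical_placements_collapse(self):
        df = pd.DataFrame(
            {"chrom": ["c"] * 3, "start": [10] * 3, "end": [110] * 3, "sample_id": ["s1"] * 3}
        )
        assert len(dedup(df)) == 1

    def test_per_sample_rule(self):
        df = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [10, 10], "end": [110, 110], "sample_id": ["s1", "s2"]}
        )
        assert len(dedup(df)) == 2

    def test_matches_set_cardinality_oracle(self):
        rng = np.random.default_rng(0)
        n = 500
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["c1", "c2"], n),
                "start": rng.integers(0, 100, n),
                "end": 0,
                "sample_id": rng.choice(["a", "b"], n),
            }
        )
        df["end"] = df["start"] + rng.integers(1, 50, n)
        expected = len({tuple(r) for r in df[["sample_id", "chrom", "start", "end"]].to_numpy()})
        shuffled = df.sample(frac=1, random_state=1)  # order-independence
        assert len(dedup(df)) == len(dedup(shuffled)) == expected


class TestCountInWindows:
    def test_boundary_spanning_fragment_counts_in_both(self):
        grid = make_windows({"c": 3000}, 1000)
        df = pd.DataFrame({"chrom": ["c"], "start": [950], "end": [1050], "sample_id": ["s"]})
        mat, _ = count_in_windows(df, grid, samples=["s"])
        assert list(mat["s"]) == [1, 1, 0]

    def test_empty_placements_give_zero_matrix(self):
        grid = make_windows({"c": 3000}, 1000)
        df = pd.DataFrame({"chrom": [], "start": [], "end": [], "sample_id": []})
        mat, skip = count_in_windows(df, grid, samples=["s"])
        assert mat["s"].sum() == 0 and not skip

    def test_unknown_chromosome_skipped_and_logged(self):
        grid = make_windows({"c": 3000}, 1000)
        df = pd.DataFrame(
            {"chrom": ["c", "zz"], "start": [0, 0], "end": [100, 100], "sample_id": ["s", "s"]}
        )
        mat, skip = count_in_windows(df, grid, samples=["s"])
        assert skip == {"zz": 1}
        assert mat["s"].sum() == 1

    def test_matches_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(6)
        grid = make_windows({"c1": 5500, "c2": 3200}, 1000)
        n = 300
        chroms = rng.choice(["c1", "c2"], n)
        starts = rng.integers(0, 5000, n)
        ends = starts + rng.integers(1, 900, n)
        df = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": ends, "sample_id": "s"}
        )
        df = df[(df["chrom"] == "c1") | (df["end"] <= 3200)].reset_index(drop=True)
        mat, _ = count_in_windows(df, grid, samples=["s"])
        frame = grid.to_frame()
        expected = np.zeros(grid.n_windows, dtype=int)
        hits_per_fragment = []
        for row in df.itertuples():
            k = 0
            for i, w in enumerate(frame.itertuples()):
                if w.chrom == row.chrom and row.start < w.end and w.start < row.end:
                    expected[i] += 1
                    k += 1
            hits_per_fragment.append(k)
        assert list(mat["s"]) == list(expected)
        # mass conservation: every fragment hits >= 1 window; totals agree
        assert all(k >= 1 for k in hits_per_fragment)
        assert mat["s"].sum() == sum(hits_per_fragment)


class TestSizeFactors:
    def test_proportional_columns(self):
        raw = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(raw)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_identical_columns_give_unit_factors(self):
        raw = pd.DataFrame({"a": [5, 7, 9], "b": [5, 7, 9], "c": [5, 7, 9]})
        assert np.allclose(size_factors(raw), 1.0)

    def test_no_all_positive_window_errors(self):
        raw = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors(raw)

    def test_matches_independent_median_of_ratios_oracle(self):
        rng = np.random.default_rng(12)
        raw = rng.poisson(50, size=(200, 12)) + 1
        sf = size_factors(pd.DataFrame(raw))
        oracle = median_of_ratios(raw.tolist())
        assert np.allclose(sf.to_numpy(), oracle)

    def test_agrees_with_deseq2_reference(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(13)
        raw = rng.poisson(80, size=(300, 6)) + 1
        sf = size_factors(pd.DataFrame(raw))
        # pydeseq2 computes size factors on a samples x genes matrix
        _, ref = pydeseq2.deseq2_norm(raw.T)
        assert np.allclose(sf.to_numpy(), ref)

    def test_normalized_columns_equalize_proportional_samples(self):
        raw = pd.DataFrame({"a": [10, 20, 30], "b": [30, 60, 90]})
        sf = size_factors(raw)
        norm = raw.div(sf, axis=1)
        assert np.allclose(norm["a"], norm["b"])


def _metagene_oracle(depth_by_chrom, gene, flank=2200, n_flank=20, n_body=50):
    """Per-base averaging oracle for one gene, plain Python."""
    d = depth_by_chrom[gene.chrom]
    lo, hi = gene.start - flank, gene.end + flank
    vec = []
    for b in range(lo, hi):
        vec.append(d[b] if 0 <= b < len(d) else np.nan)
    if gene.strand == "-":
        vec = vec[::-1]

    def bins(v, k):
        edges = np.linspace(0, len(v), k + 1).round().astype(int)
        return [np.nanmean(v[edges[i]:edges[i + 1]]) if edges[i] < edges[i + 1] else np.nan
                for i in range(k)]

    v = np.array(vec)
    body_len = gene.end - gene.start
    return (
        bins(v[:flank], n_flank)
        + bins(v[flank:flank + body_len], n_body)
        + bins(v[flank + body_len:], n_flank)
    )


class TestProfiles:
    def test_constant_depth_gives_flat_profile(self):
        grid = make_windows({"c": 100_000}, 1000)
        vals = np.full(grid.n_windows, 3.0 * 1000)  # per-base depth 3.0
        genes = [Gene("g", "c", 50_000, 60_000, "+")]
        prof = metagene_profile(vals, grid, genes)
        assert np.allclose(prof.values, 3.0)
        assert len(prof.values) == 90

    def test_step_profile_upstream_zero_body_elevated(self):
        grid = make_windows({"c": 100_000}, 1000)
        vals = np.zeros(grid.n_windows)
        vals[50:60] = 5.0 * 1000  # gene body windows only
        genes = [Gene("g", "c", 50_000, 60_000, "+")]
        prof = metagene_profile(vals, grid, genes)
        assert np.allclose(prof.values[20:70], 5.0)
        assert np.allclose(prof.values[:20], 0.0)
        assert np.allclose(prof.values[70:], 0.0)

    def test_matches_per_base_oracle_on_toy_genes(self):
        rng = np.random.default_rng(21)
        grid = make_windows({"c": 60_000}, 1000)
        vals = rng.gamma(2.0, 50.0, size=grid.n_windows)
        genes = [
            Gene("g1", "c", 10_000, 13_500, "+"),
            Gene("g2", "c", 20_000, 24_000, "-"),
            Gene("g3", "c", 40_000, 41_200, "+"),
            Gene("g4", "c", 1_000, 4_000, "-"),  # upstream flank clipped at the edge
        ]
        depth = {}
        for chrom in grid.chroms:
            L = grid.genome_lengths[chrom]
            per_base = np.empty(L)
            for i in range(grid.n_windows):
                w = grid.window_interval(i)
                per_base[w.start:w.end] = vals[i] / w.length
            depth[chrom] = per_base
        expected = np.nanmean(
            [_metagene_oracle(depth, g) for g in genes], axis=0
        )
        prof = metagene_profile(vals, grid, genes)
        assert np.allclose(prof.values, expected, equal_nan=True)

    def test_strand_orientation_mirrors_profile(self):
        # mirroring the whole scene (reversed depth, reflected gene on the
        # other strand) must leave the oriented profile unchanged
        grid = make_windows({"c": 100_000}, 1000)
        rng = np.random.default_rng(17)
        vals = rng.gamma(2.0, 30.0, size=grid.n_windows) * 1000
        plus = metagene_profile(vals, grid, [Gene("g", "c", 50_000, 60_000, "+")])
        minus = metagene_profile(
            vals[::-1].copy(), grid, [Gene("g", "c", 40_000, 50_000, "-")]
        )
        assert np.allclose(plus.values, minus.values)

    def test_empty_gene_group_errors(self):
        grid = make_windows({"c": 10_000}, 1000)
        with pytest.raises(ValueError, match="empty"):
            metagene_profile(np.ones(grid.n_windows), grid, [], group="none")

    def test_cgi_profile_flat_and_peaked(self):
        grid = make_windows({"c": 100_000}, 1000)
        flat = cgi_profile(np.full(grid.n_windows, 2.0 * 1000), grid,
                           [GenomicInterval("c", 50_000, 52_000)])
        assert np.allclose(flat, 2.0)
        vals = np.zeros(grid.n_windows)
        vals[50:52] = 4.0 * 1000
        peaked = cgi_profile(vals, grid, [GenomicInterval("c", 50_000, 52_000)])
        assert np.allclose(peaked[20:40], 4.0)
        assert peaked[:19].max() == 0.0 and peaked[41:].max() == 0.0


class TestSubtelomeric:
    def test_matches_textbook_two_sample_formula(self):
        grid = make_windows({"c": 30_000}, 1000)
        rng = np.random.default_rng(3)
        vals = rng.gamma(3.0, 10.0, size=grid.n_windows)
        out = subtelomeric_test(vals, grid, span_bp=5000)
        sub = np.r_[vals[:5], vals[-5:]]
        rest = vals[5:-5]
        assert out.loc[0, "t"] == pytest.approx(two_sample_t(sub.tolist(), rest.tolist()))

    def test_strong_shift_is_significant(self):
        grid = make_windows({"c": 30_000}, 1000)
        rng = np.random.default_rng(4)
        vals = rng.normal(10, 1, size=grid.n_windows)
        vals[:5] += 5
        vals[-5:] += 5
        out = subtelomeric_test(vals, grid, span_bp=5000)
        assert out.loc[0, "p_value"] < 0.01
        assert out.loc[0, "mean_subtelomeric"] > out.loc[0, "mean_rest"]

    def test_short_chromosomes_skipped(self):
        grid = make_windows({"c": 9000}, 1000)
        out = subtelomeric_test(np.ones(grid.n_windows), grid, span_bp=5000)
        assert out.empty


class TestSaturation:
    @pytest.fixture()
    def placements(self):
        # heterogeneous window intensities, as in real enrichment data;
        # uniform placements would leave nothing for the halves to agree on
        rng = np.random.default_rng(8)
        rates = rng.gamma(0.5, 2.0, size=50)
        windows = rng.choice(50, size=4000, p=rates / rates.sum())
        starts = windows * 1000 + rng.integers(0, 800, size=4000)
        return pd.DataFrame(
            {"chrom": "c", "start": starts, "end": starts + 200, "sample_id": "s"}
        )

    def test_bit_reproducible_under_seed(self, placements):
        grid = make_windows({"c": 50_000}, 1000)
        a = saturation(placements, grid, seed=5)
        b = saturation(placements, grid, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_full_fraction_correlates_highly(self, placements):
        grid = make_windows({"c": 50_000}, 1000)
        out = saturation(placements, grid, fractions=(0.1, 1.0), seed=5)
        assert out.loc[1, "pearson_r"] > out.loc[0, "pearson_r"] - 0.2
        assert out.loc[1, "pearson_r"] > 0.5

    def test_invalid_fraction_rejected(self, placements):
        grid = make_windows({"c": 50_000}, 1000)
        with pytest.raises(ValueError):
            saturation(placements, grid, fractions=(0.0,), seed=1)

    def test_requires_enough_placements(self):
        grid = make_windows({"c": 50_000}, 1000)
        small = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100], "sample_id": ["s"]})
        with pytest.raises(ValueError):
            saturation(small, grid, seed=1)


class TestCoupling:
    def test_counts_cpgs_per_window(self):
        grid = make_windows({"c": 2000}, 1000)
        vec = coupling(grid, {"c": "CG" * 500 + "A" * 1000})
        assert list(vec) == [500, 0]

    def test_matches_string_counting_oracle(self):
        rng = np.random.default_rng(10)
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, 3500)])
        grid = make_windows({"c": 3500}, 1000)
        vec = coupling(grid, {"c": seq})
        for i in range(grid.n_windows):
            w = grid.window_interval(i)
            assert vec[i] == seq[w.start:w.end].count("CG")
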