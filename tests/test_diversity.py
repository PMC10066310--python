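import math

import numpy as np
import pytest

from divprof import (
    IDENTITY,
    DistanceChunk,
    ParameterGrid,
    ValidationError,
    diversity_grid,
    diversity_grid_dense,
    iter_distance_chunks,
    kernel_weighted_abundance,
    ln_naive_diversity,
    make_uniform_mock,
    mean_pairwise_distance,
    naive_diversity,
    read_diversity_table,
    similarity_scaled_diversity,
    write_diversity_table,
)
from divprof.errors import FormatError
from conftest import random_frequencies
from oracles import brute_force_grid, brute_force_ln_diversity


class TestNaiveDiversity:
    @pytest.mark.parametrize(
        "q,expected",
        [
            (0.0, 3.0),
            (1.0, math.exp(-(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25)))),
            (2.0, 1 / 0.375),
            (math.inf, 2.0),
        ],
    )
    def test_three_clone_closed_forms(self, three_clone_freqs, q, expected):
        assert naive_diversity(three_clone_freqs, q) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0, 3.5, 6.0, math.inf])
    def test_uniform_equals_richness_for_every_q(self, q):
        p = np.full(100, 0.01)
        assert naive_diversity(p, q) == pytest.approx(100.0, rel=1e-12)

    def test_bounded_between_one_and_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = random_frequencies(rng, int(rng.integers(2, 60)))
            for q in (0.0, 0.5, 1.0, 2.0, 6.0, math.inf):
                d = naive_diversity(p, q)
                assert 1.0 - 1e-12 <= d <= len(p) + 1e-9

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = random_frequencies(rng, 20)
            for q in (0.0, 1.0, 2.0, 4.0, math.inf):
                assert ln_naive_diversity(p, q) == pytest.approx(
                    brute_force_ln_diversity(p, None, q, math.inf), abs=1e-9
                )

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            naive_diversity(np.array([0.5, 0.6]), 2.0)

    def test_slope_at_q1_is_half_log_variance(self):
        # analytic d(ln D)/dq at q=1 equals -Var_p(ln p)/2
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = random_frequencies(rng, 30)
            logp = np.log(p)
            mu = float(p @ logp)
            analytic = -0.5 * float(p @ (logp - mu) ** 2)
            h = 1e-5
            numeric = (
                ln_naive_diversity(p, 1.0 + h) - ln_naive_diversity(p, 1.0 - h)
            ) / (2 * h)
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-12)

    def test_slope_magnitude_tracks_log_frequency_variance(self):
        # two-point family p = (a, 1-a): Var_p(ln p) rises with a on
        # [0.55, 0.85], and the numerical fall of ln D at q=1 rises with it
        h = 1e-5
        slopes, variances = [], []
        for a in (0.55, 0.65, 0.75, 0.85):
            p = np.array([a, 1 - a])
            logp = np.log(p)
            variances.append(float(p @ (logp - p @ logp) ** 2))
            slopes.append(
                abs(
                    (ln_naive_diversity(p, 1 + h) - ln_naive_diversity(p, 1 - h))
                    / (2 * h)
                )
            )
        assert variances == sorted(variances)
        assert slopes == sorted(slopes)


class TestKernelWeightedAbundance:
    def test_lambda_zero_gives_ones(self, three_clone_freqs):
        chunk = DistanceChunk(0, np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]),
                              "blosum45")
        np.testing.assert_allclose(
            kernel_weighted_abundance(chunk, three_clone_freqs, 0.0), np.ones(3)
        )

    def test_identity_sentinel_returns_frequencies(self, three_clone_freqs):
        chunk = DistanceChunk(0, np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]),
                              "blosum45")
        np.testing.assert_array_equal(
            kernel_weighted_abundance(chunk, three_clone_freqs, IDENTITY),
            three_clone_freqs,
        )

    def test_two_clone_fixture(self):
        rep, dist = make_uniform_mock(2, 1.0)
        chunk = DistanceChunk(0, dist, "blosum45")
        zp = kernel_weighted_abundance(chunk, rep.frequencies, math.log(2))
        np.testing.assert_allclose(zp, [0.75, 0.75])

    def test_negative_lambda_rejected(self, three_clone_freqs):
        chunk = DistanceChunk(0, np.zeros((3, 3)), "blosum45")
        with pytest.raises(ValidationError):
            kernel_weighted_abundance(chunk, three_clone_freqs, -0.1)

    def test_bounded_by_frequency_and_one(self):
        rng = np.random.default_rng(3)
        p = random_frequencies(rng, 25)
        d = rng.uniform(0, 2, size=(25, 25))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        for lam in (0.1, 1.0, 64.0):
            zp = kernel_weighted_abundance(DistanceChunk(0, d, "blosum45"), p, lam)
            assert np.all(zp >= p - 1e-12)
            assert np.all(zp <= 1 + 1e-12)


class TestSimilarityScaledDiversity:
    def test_lambda_zero_collapses_to_one(self, three_clone_freqs):
        zp = np.ones(3)
        for q in (0.0, 1.0, 2.0, 6.0, math.inf):
            assert similarity_scaled_diversity(three_clone_freqs, zp, q) == (
                pytest.approx(1.0, abs=1e-12)
            )

    def test_two_clone_fixture_q2(self):
        p = np.array([0.5, 0.5])
        assert similarity_scaled_diversity(p, np.array([0.75, 0.75]), 2.0) == (
            pytest.approx(4 / 3, rel=1e-12)
        )

    def test_identity_zp_recovers_naive(self, three_clone_freqs, grid):
        for q in grid.q_values:
            assert similarity_scaled_diversity(
                three_clone_freqs, three_clone_freqs, q
            ) == pytest.approx(naive_diversity(three_clone_freqs, q), rel=1e-12)

    def test_q1_and_qinf_are_limits_of_the_general_formula(self):
        rng = np.random.default_rng(4)
        p = random_frequencies(rng, 30)
        d = rng.uniform(0.05, 1.5, size=(30, 30))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        zp = np.exp(-0.8 * d) @ p
        at_1 = similarity_scaled_diversity(p, zp, 1.0)
        for q in (1 - 1e-4, 1 + 1e-4):
            assert similarity_scaled_diversity(p, zp, q) == pytest.approx(
                at_1, rel=1e-3
            )
        assert similarity_scaled_diversity(p, zp, 400.0) == pytest.approx(
            similarity_scaled_diversity(p, zp, math.inf), rel=2e-2
        )

    def test_out_of_bounds_zp_rejected(self, three_clone_freqs):
        with pytest.raises(ValidationError):
            similarity_scaled_diversity(three_clone_freqs, np.array([1.5, 1, 1]), 2)
        with pytest.raises(ValidationError):
            similarity_scaled_diversity(
                three_clone_freqs, np.array([0.1, 0.9, 0.9]), 2
            )


class TestDiversityGrid:
    def test_single_clone_grid_is_all_zero(self, grid):
        dg = diversity_grid_dense(np.array([1.0]), np.zeros((1, 1)), grid, "one")
        assert np.all(dg.log_values == 0.0)

    def test_chunked_grid_matches_brute_force_oracle(
        self, sequence_repertoire, grid
    ):
        for metric in ("blosum45", "atchley"):
            chunks = list(
                iter_distance_chunks(sequence_repertoire, metric, chunk_size=7)
            )
            dense = np.vstack([c.values for c in chunks])
            dg = diversity_grid(sequence_repertoire, iter(chunks), grid)
            expected = brute_force_grid(
                sequence_repertoire.frequencies, dense,
                grid.q_values, grid.lambda_values,
            )
            np.testing.assert_allclose(
                dg.log_values, np.maximum(expected, 0), atol=1e-9
            )

    def test_grid_independent_of_chunk_size(self, sequence_repertoire, small_grid):
        reference = None
        for chunk_size in (1, 7, 100):
            chunks = iter_distance_chunks(
                sequence_repertoire, "atchley", chunk_size=chunk_size
            )
            dg = diversity_grid(sequence_repertoire, chunks, small_grid)
            if reference is None:
                reference = dg.log_values
            else:
                # distance chunks are bit-identical across chunk sizes; the
                # accumulated (Zp) sums may differ by summation order only
                np.testing.assert_allclose(dg.log_values, reference, atol=1e-12)

    def test_monotonicity_invariants_on_random_repertoires(self, small_grid):
        rng = np.random.default_rng(6)
        for trial in range(20):
            S = int(rng.integers(3, 40))
            p = random_frequencies(rng, S)
            d = rng.uniform(0, 2, size=(S, S))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            dg = diversity_grid_dense(p, d, small_grid, f"r{trial}")
            ln_S = math.log(S)
            # non-increasing in q along every lambda column
            assert np.all(np.diff(dg.log_values, axis=0) <= 1e-9)
            # non-decreasing in lambda (identity last) along every q row
            assert np.all(np.diff(dg.log_values, axis=1) >= -1e-9)
            # sandwich: 0 <= ln D <= ln D(identity) <= ln S
            assert np.all(dg.log_values >= 0)
            assert np.all(dg.log_values[:, -1] <= ln_S + 1e-9)
            assert np.all(
                dg.log_values <= dg.log_values[:, [-1]] + 1e-9
            )

    def test_small_lambda_perturbation_expansion(self, small_grid):
        # ln D(q, lambda) ~ lambda * d-bar for lambda << 1/d-bar, any q
        rng = np.random.default_rng(7)
        for _ in range(5):
            S = 40
            p = random_frequencies(rng, S)
            d = rng.uniform(0.2, 1.0, size=(S, S))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            dbar = mean_pairwise_distance(p, d)
            lam = 0.1 / dbar * 0.5  # safely inside the linear regime
            grid = ParameterGrid(
                q_values=(0.0, 1.0, 2.0, 6.0), lambda_values=(0.0, lam, math.inf)
            )
            dg = diversity_grid_dense(p, d, grid, "pert")
            vals = dg.log_values[:, 1]
            assert np.all(np.abs(vals - lam * dbar) <= 0.05 * lam * dbar)

    def test_q_independence_of_small_lambda_spacing_on_uniform_mock(self):
        rep, dist = make_uniform_mock(100, 0.2)
        grid = ParameterGrid(
            q_values=(0.0, 1.0, 2.0, 6.0), lambda_values=(0.0, 0.05, math.inf)
        )
        dg = diversity_grid_dense(rep.frequencies, dist, grid, "uni")
        spread = dg.log_values[:, 1].max() - dg.log_values[:, 1].min()
        assert spread < 1e-6

    def test_manifest_mismatch_rejected(self, tmp_path, sequence_repertoire):
        from divprof import write_distance_chunks

        manifest = write_distance_chunks(
            sequence_repertoire, tmp_path, "atchley", chunk_size=10
        )
        other, _ = make_uniform_mock(sequence_repertoire.richness, 0.5)
        with pytest.raises(ValidationError):
            diversity_grid(other, manifest)


class TestDiversityTableIO:
    def test_grid_cardinality_and_round_trip(self, tmp_path, grid):
        rng = np.random.default_rng(8)
        p = random_frequencies(rng, 12)
        d = rng.uniform(0, 1, size=(12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dg = diversity_grid_dense(p, d, grid, "rt")
        path = write_diversity_table(dg, tmp_path / "div.tsv")
        n_rows = len(path.read_text().strip().split("\n")) - 1
        assert n_rows == 8 * 17
        back = read_diversity_table(path)
        assert back.sample_id == "rt"
        assert back.grid == dg.grid
        np.testing.assert_array_equal(back.log_values, dg.log_values)

    def test_D_column_is_exp_of_lnD(self, tmp_path, small_grid):
        rep, dist = make_uniform_mock(10, 0.3)
        dg = diversity_grid_dense(rep.frequencies, dist, small_grid, "exp")
        path = write_diversity_table(dg, tmp_path / "e.tsv")
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(df["D"], np.exp(df["ln_D"]), rtol=1e-12)

    def test_unknown_sentinel_token_rejected(self, tmp_path, small_grid):
        rep, dist = make_uniform_mock(4, 0.5)
        dg = diversity_grid_dense(rep.frequencies, dist, small_grid, "tok")
        path = write_diversity_table(dg, tmp_path / "t.tsv")
        bad = path.read_text().replace("identity", "forever")
        path.write_text(bad)
        with pytest.raises(FormatError):
            read_diversity_table(path)
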