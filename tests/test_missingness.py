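"""Block partitioning, profile fitting/replay, the beta baseline, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomiss import (
    BetaMissingness,
    FixtureSpec,
    MISSING,
    Track,
    apply_beta,
    apply_profile,
    fit_beta,
    fit_profile,
    generate_matrix,
    partition_blocks,
    summarize_missingness,
)

from conftest import build_matrix


class TestPartition:
    def test_floor_remainder_rule_by_hand(self):
        assert list(partition_blocks(10, 3).block_sizes) == [4, 3, 3]
        assert list(partition_blocks(7, 7).block_sizes) == [1] * 7
        assert list(partition_blocks(5, 1).block_sizes) == [5]

    def test_replicate_larger_than_empirical_is_rejected(self):
        with pytest.raises(ValueError, match="more sites than empirical"):
            partition_blocks(10, 11)
        with pytest.raises(ValueError):
            partition_blocks(0, 1)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(1, 10**6), st.data())
    def test_partition_law(self, N, data):
        M = data.draw(st.integers(1, N))
        part = partition_blocks(N, M)
        sizes = part.block_sizes
        assert sizes.sum() == N
        assert len(sizes) == M
        base, rem = divmod(N, M)
        assert np.array_equal(sizes[:rem], np.full(rem, base + 1))
        assert np.array_equal(sizes[rem:], np.full(M - rem, base))

    @pytest.mark.parametrize(
        "M, expected_min",
        [(3327, 28), (6612, 14), (9657, 9), (12659, 7), (16468, 5),
         (19930, 4), (23012, 4), (25682, 3), (29391, 3), (33023, 2)],
    )
    def test_minimal_block_size_for_large_empirical_segment(self, M, expected_min):
        """Partitioning a 93,166-site segment into the segregating-site
        counts of 1-10 Mb coalescent replicates yields these minimal block
        sizes."""
        assert partition_blocks(93166, M).block_sizes.min() == expected_min


class TestProfile:
    def test_hand_derived_blocks(self):
        # N=4, M=2 -> blocks {1,2}, {3,4}; sample s1 missing at sites 1, 2
        m = build_matrix(
            [
                ("1", 1, ("A", "T"), ["./.", "0/0"]),
                ("1", 2, ("A", "T"), ["./.", "0/1"]),
                ("1", 3, ("A", "T"), ["0/1", "./."]),
                ("1", 4, ("A", "T"), ["1/1", "0/0"]),
            ]
        )
        profile = fit_profile(m, 2)
        assert np.array_equal(profile.p, [[1.0, 0.0], [0.0, 0.5]])

    def test_identity_partition_recovers_indicator_matrix(self):
        spec = FixtureSpec(S=6, N=40, tracks=(Track(3, 11, 25),),
                           background_missing=0.3, seed=7)
        m = generate_matrix(spec)
        profile = fit_profile(m, m.n_sites)
        assert np.array_equal(profile.p, m.missing_mask().T.astype(float))
        assert (profile.p[2, 10:25] == 1.0).all()

    def test_all_or_none_missing_rows(self):
        m = build_matrix(
            [("1", p, ("A", "T"), ["./.", "0/0"]) for p in (1, 2, 3, 4, 5, 6)]
        )
        profile = fit_profile(m, 3)
        assert (profile.p[0] == 1.0).all()
        assert (profile.p[1] == 0.0).all()

    def test_oracle_equivalence_on_random_small_cases(self, rng):
        """fit_profile matches a brute-force per-block recount."""
        for _ in range(20):
            S, N = int(rng.integers(1, 6)), int(rng.integers(2, 15))
            M = int(rng.integers(1, N + 1))
            mask = rng.random((N, S)) < 0.4
            m = build_matrix(
                [
                    ("1", i + 1, ("A", "T"),
                     ["./." if mask[i, j] else "0/1" for j in range(S)])
                    for i in range(N)
                ]
            )
            profile = fit_profile(m, M)
            sizes = partition_blocks(N, M).block_sizes
            start = 0
            for j, size in enumerate(sizes):
                for i in range(S):
                    expected = mask[start : start + size, i].mean()
                    assert profile.p[i, j] == pytest.approx(expected)
                start += size


class TestApplyProfile:
    @staticmethod
    def make_uniform_profile(M, S, p):
        from genomiss.missingness import MissingnessProfile

        return MissingnessProfile(
            S, partition_blocks(M, M), np.full((S, M), float(p))
        )

    def test_extreme_probabilities(self, rng):
        rep = generate_matrix(FixtureSpec(S=5, N=20, seed=3))
        all_on = self.make_uniform_profile(20, 4, 1.0)
        masked = apply_profile(rep, all_on, rng)
        assert masked.missing_mask().all()
        assert not masked.phased.any()
        all_off = self.make_uniform_profile(20, 4, 0.0)
        assert apply_profile(rep, all_off, rng).equals(rep)

    def test_site_count_mismatch_is_rejected(self, rng):
        rep = generate_matrix(FixtureSpec(S=5, N=20, seed=3))
        with pytest.raises(ValueError, match="sites"):
            apply_profile(rep, self.make_uniform_profile(19, 4, 0.5), rng)

    def test_masking_is_conservative(self, rng):
        rep = generate_matrix(FixtureSpec(S=8, N=60, tracks=(Track(1, 1, 30),),
                                          background_missing=0.2, seed=11))
        profile = self.make_uniform_profile(60, 4, 0.5)
        masked = apply_profile(rep, profile, rng)
        before, after = rep.missing_mask(), masked.missing_mask()
        assert (after | before == after).all()  # missing-set only grows
        untouched = ~after
        assert np.array_equal(rep.codes[untouched], masked.codes[untouched])

    def test_masking_expectation_matches_binomial(self):
        """Aggregate masked fraction over many runs sits within 3 MC SDs."""
        p = 0.3
        T, M, runs = 50, 200, 1000
        rep = generate_matrix(FixtureSpec(S=T, N=M, seed=5))
        profile = self.make_uniform_profile(M, 4, p)
        rng = np.random.default_rng(12345)
        total = sum(
            apply_profile(rep, profile, rng).missing_mask().sum()
            for _ in range(runs)
        )
        n_draws = runs * T * M
        frac = total / n_draws
        sd = np.sqrt(p * (1 - p) / n_draws)
        assert abs(frac - p) < 3 * sd

    def test_expected_site_rate_is_mean_over_samples(self):
        """With heterogeneous p_sj, the per-site masked fraction converges to
        mean_s(p_sj) — checked against an independent per-draw resampler."""
        rng_p = np.random.default_rng(77)
        S, M, T, runs = 5, 10, 40, 400
        p = rng_p.random((S, M))
        rep = generate_matrix(FixtureSpec(S=T, N=M, seed=5))
        from genomiss.missingness import MissingnessProfile, partition_blocks

        profile = MissingnessProfile(S, partition_blocks(M, M), p)
        rng = np.random.default_rng(99)
        counts = np.zeros(M)
        for _ in range(runs):
            counts += apply_profile(rep, profile, rng).missing_mask().sum(axis=1)
        observed = counts / (runs * T)

        # brute-force resampler: one uniform s and one Bernoulli per draw
        oracle_rng = np.random.default_rng(314)
        oracle = np.zeros(M)
        for _ in range(runs):
            for t in range(T):
                for j in range(M):
                    s = oracle_rng.integers(S)
                    if oracle_rng.random() < p[s, j]:
                        oracle[j] += 1
        oracle /= runs * T
        expected = p.mean(axis=0)
        sd = np.sqrt(expected * (1 - expected) / (runs * T))
        assert (np.abs(observed - expected) < 4 * sd).all()
        assert (np.abs(oracle - expected) < 4 * sd).all()

    def test_seeded_determinism(self):
        rep = generate_matrix(FixtureSpec(S=6, N=30, seed=2))
        profile = self.make_uniform_profile(30, 3, 0.4)
        a = apply_profile(rep, profile, np.random.default_rng(42))
        b = apply_profile(rep, profile, np.random.default_rng(42))
        assert a.equals(b)


class TestBeta:
    def test_method_of_moments_by_hand(self):
        params = BetaMissingness.from_moments(0.5, 0.25)
        assert params.alpha == pytest.approx(1.5)
        assert params.beta == pytest.approx(1.5)

    def test_ancient_sample_moments(self):
        """The reported aDNA per-site missingness moments (mean 0.55,
        SD 0.21) give these shapes: nu = .55*.45/.21^2 - 1."""
        params = BetaMissingness.from_moments(0.55, 0.21)
        nu = 0.55 * 0.45 / 0.21**2 - 1
        assert params.alpha == pytest.approx(0.55 * nu)
        assert params.beta == pytest.approx(0.45 * nu)
        assert params.alpha == pytest.approx(2.536734694)
        assert params.beta == pytest.approx(2.075510204)

    def test_symmetric_mean_gives_equal_shapes(self):
        p = BetaMissingness.from_moments(0.5, 0.1)
        assert p.alpha == p.beta

    @pytest.mark.parametrize("mean, sd", [(0.0, 0.1), (1.0, 0.1), (0.5, 0.5),
                                          (0.5, 0.0), (0.1, 0.31)])
    def test_invalid_moments_are_rejected(self, mean, sd):
        with pytest.raises(ValueError):
            BetaMissingness.from_moments(mean, sd)

    def test_fit_beta_from_matrix_matches_summary_moments(self):
        m = generate_matrix(FixtureSpec(S=20, N=200, background_missing=0.4,
                                        seed=9))
        params = fit_beta(m)
        summary = summarize_missingness(m)
        assert params.mean == pytest.approx(summary.mean)
        assert params.sd == pytest.approx(summary.sd)
        assert params.alpha / (params.alpha + params.beta) == pytest.approx(
            params.mean
        )

    def test_apply_beta_total_expectation(self):
        """Overall masked fraction converges to the beta mean."""
        rep = generate_matrix(FixtureSpec(S=50, N=400, seed=4))
        params = BetaMissingness.from_moments(0.5, 0.15)
        rng = np.random.default_rng(8)
        fracs = [
            apply_beta(rep, params, rng).missing_mask().mean()
            for _ in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)

    def test_apply_beta_near_zero_mean_masks_almost_nothing(self):
        rep = generate_matrix(FixtureSpec(S=30, N=300, seed=4))
        params = BetaMissingness.from_moments(0.001, 0.0005)
        masked = apply_beta(rep, params, np.random.default_rng(1))
        assert masked.missing_mask().mean() < 0.01

    def test_apply_beta_seeded_determinism_and_conservation(self):
        rep = generate_matrix(FixtureSpec(S=10, N=100, background_missing=0.1,
                                          seed=6))
        params = BetaMissingness.from_moments(0.3, 0.1)
        a = apply_beta(rep, params, np.random.default_rng(5))
        b = apply_beta(rep, params, np.random.default_rng(5))
        assert a.equals(b)
        assert (a.missing_mask() | rep.missing_mask() == a.missing_mask()).all()


class TestSummaries:
    def test_two_by_two_enumeration(self):
        m = build_matrix(
            [("1", 1, ("A", "T"), ["./.", "0/1"]),
             ("1", 2, ("A", "T"), ["0/0", "1/1"])]
        )
        s = summarize_missingness(m)
        assert list(s.per_site) == [0.5, 0.0]
        assert list(s.per_sample) == [0.5, 0.0]
        assert s.mean == 0.25
        assert s.sd == 0.25

    def test_fully_called_matrix_is_all_zero(self):
        m = generate_matrix(FixtureSpec(S=4, N=10, seed=1))
        s = summarize_missingness(m)
        assert not s.per_site.any() and not s.per_sample.any()

    def test_double_counting_identity(self):
        m = generate_matrix(FixtureSpec(S=7, N=50, background_missing=0.3,
                                        seed=2))
        s = summarize_missingness(m)
        assert s.per_site.mean() == pytest.approx(s.per_sample.mean())

    def test_report_files_are_tab_separated(self, tmp_path):
        import pandas as pd

        from genomiss import write_sample_missingness, write_site_missingness

        m = build_matrix(
            [("1", 1, ("A", "T"), ["./.", "0/1"]),
             ("1", 2, ("A", "T"), ["0/0", "./."])]
        )
        write_site_missingness(m, tmp_path / "r.vmiss")
        write_sample_missingness(m, tmp_path / "r.smiss")
        vmiss = pd.read_csv(tmp_path / "r.vmiss", sep="\t")
        assert list(vmiss.columns) == ["CHROM", "POS", "N_MISS", "F_MISS"]
        assert list(vmiss.F_MISS) == [0.5, 0.5]
        smiss = pd.read_csv(tmp_path / "r.smiss", sep="\t")
        assert list(smiss.N_MISS) == [1, 1]
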