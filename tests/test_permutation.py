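from collections import Counter

import numpy as np
import pytest

from wireworm.association import chi_square_2x2, contingency_from_pairs
from wireworm.data import DataError, Species
from wireworm.permutation import permutation_test, permute_within_fields
from wireworm.simulate import GeneratorConfig, generate_dataset

from conftest import make_pairs


def _sim_pairs(b, sigma_f, n_fields, pts, seed):
    cfg = GeneratorConfig(
        n_fields=n_fields, points_per_field=pts, field_effect_sd=sigma_f,
        soil_mean=0.3, soil_theta=1.0, soil_zi=0.0,
        trap_intercept=0.0, trap_slope=b, trap_theta=1.0, trap_zi=0.0,
        seed=seed,
    )
    ds = generate_dataset(cfg, Species.A_brevis)
    return list(ds)


class TestPermuteWithinFields:
    def test_single_pair_field_unchanged(self, rng):
        pairs = make_pairs([1], [4])
        assert permute_within_fields(pairs, rng) == pairs

    def test_per_field_multisets_conserved(self, rng):
        pairs = _sim_pairs(0.8, 0.5, 6, 20, seed=2)
        permuted = permute_within_fields(pairs, rng)
        for fid in {p.field_id for p in pairs}:
            orig = [p for p in pairs if p.field_id == fid]
            perm = [p for p in permuted if p.field_id == fid]
            assert Counter(p.soil_count for p in orig) == Counter(p.soil_count for p in perm)
            assert Counter(p.trap_count for p in orig) == Counter(p.trap_count for p in perm)

    def test_uniform_over_permutation_group(self, rng):
        """3 distinct trap values: each of the 6 pairings at frequency 1/6."""
        pairs = make_pairs([0, 1, 2], [10, 20, 30])
        n_draws = 6000
        seen = Counter()
        for _ in range(n_draws):
            perm = permute_within_fields(pairs, rng)
            seen[tuple(p.trap_count for p in perm)] += 1
        assert len(seen) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / n_draws)
        for count in seen.values():
            assert abs(count / n_draws - 1 / 6) < 3 * se


class TestPermutationTest:
    def test_observed_stat_is_yates_chi2(self):
        pairs = _sim_pairs(0.8, 0.4, 8, 30, seed=5)
        res = permutation_test(pairs, n_perm=100, seed=0)
        expected = chi_square_2x2(
            contingency_from_pairs(pairs), continuity_correction=True
        ).statistic
        assert res.observed_stat == pytest.approx(expected)

    def test_determinism_and_add_one_never_zero(self):
        pairs = _sim_pairs(1.5, 0.0, 4, 40, seed=9)
        r1 = permutation_test(pairs, n_perm=3000, seed=11)
        r2 = permutation_test(pairs, n_perm=3000, seed=11)
        assert r1.p_perm == r2.p_perm > 0.0

    def test_zero_margin_errors(self):
        pairs = make_pairs([0, 0, 1], [1, 2, 3])  # no trap absences
        with pytest.raises(DataError):
            permutation_test(pairs, n_perm=10)

    def test_matches_literal_repairing_null(self, rng):
        """The sampled null distribution equals the one from materialized
        re-pairings (same data, moderate replicate count)."""
        from wireworm.association import yates_chi2_statistic

        pairs = _sim_pairs(0.6, 0.5, 5, 12, seed=13)
        res = permutation_test(pairs, n_perm=4000, seed=21, keep_null=True)
        literal = np.empty(4000)
        for i in range(4000):
            t = contingency_from_pairs(permute_within_fields(pairs, rng))
            literal[i] = chi_square_2x2(t, continuity_correction=True).statistic
        # compare distributions by mean and tail mass
        assert np.mean(res.null_stats) == pytest.approx(
            np.mean(literal), abs=4 * np.std(literal) / np.sqrt(4000)
        )
        # small offset so the comparison is robust to float noise at the
        # atoms of the discrete null
        thr = res.observed_stat - 1e-9
        assert np.mean(res.null_stats >= thr) == pytest.approx(
            np.mean(literal >= thr), abs=0.03
        )

    def test_single_field_null_matches_hypergeometric_mean(self):
        """With one field the permutation null is the conditional
        hypergeometric null; compare the null mean with exact enumeration."""
        from scipy.stats import hypergeom

        from wireworm.association import ContingencyTable2x2

        pairs = make_pairs([0, 0, 0, 0, 1, 1, 1], [0, 0, 1, 1, 0, 1, 1])
        res = permutation_test(pairs, n_perm=20_000, seed=3, keep_null=True)
        n, s, t = 7, 3, 4  # points, soil-present, trap-present
        rv = hypergeom(n, s, t)
        exact_mean = 0.0
        for d in range(max(0, s + t - n), min(s, t) + 1):
            table = ContingencyTable2x2(n - s - (t - d), t - d, s - d, d)
            stat = chi_square_2x2(table, continuity_correction=True).statistic
            exact_mean += rv.pmf(d) * stat
        mc_se = np.std(res.null_stats) / np.sqrt(res.n_perm)
        assert np.mean(res.null_stats) == pytest.approx(exact_mean, abs=4 * mc_se)

    def test_power_under_strong_point_level_link(self):
        """Large soil->trap slope at ~500 points: p < 0.05 in > 80% of replicates."""
        rejections = 0
        n_rep = 40
        for i in range(n_rep):
            pairs = _sim_pairs(b=2.0, sigma_f=0.3, n_fields=10, pts=50, seed=1000 + i)
            res = permutation_test(pairs, n_perm=2000, seed=i)
            rejections += res.p_perm < 0.05
        assert rejections / n_rep > 0.8

    def test_type_i_error_under_site_aggregation_only(self):
        """b = 0 with field effects only: rejection rate at alpha=0.05 stays
        within 0.05 +/- 0.02 over 500 simulated datasets."""
        alpha = 0.05
        rejections = 0
        n_datasets = 500
        for i in range(n_datasets):
            pairs = _sim_pairs(b=0.0, sigma_f=0.7, n_fields=8, pts=25, seed=5000 + i)
            try:
                res = permutation_test(pairs, n_perm=2000, seed=i)
            except DataError:  # degenerate margin in a small simulated draw
                continue
            rejections += res.p_perm <= alpha
        rate = rejections / n_datasets
        assert abs(rate - alpha) < 0.02
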