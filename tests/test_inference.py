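import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rhythmflow as rf
from rhythmflow.errors import PairingError, StateError
from rhythmflow.inference import (
    CohortTable,
    NullDistribution,
    build_cohort_table,
    permutation_test,
    repair_null,
    session_comparison,
    session_symbol_matrix,
)
from rhythmflow.symbolic import SymbolSeries, symbolize


def _individuals(n, T=120, seed=0):
    rng = np.random.default_rng(seed)
    return [symbolize(rng.random(T)) for _ in range(n)]


class TestRepairNull:
    def test_four_individuals_enumerate_three_matchings(self):
        """With 4 players there are exactly 3 perfect matchings; a long run
        must visit each with frequency 1/3."""
        inds = _individuals(4, seed=1)
        null = repair_null(inds, "mi", n_reps=3000, seed=2)
        # every resampled mean must equal the mean of one of the 3 matchings
        from rhythmflow.information import mutual_information as mi

        matchings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        expected = sorted(
            np.mean([mi(inds[i], inds[j]) for i, j in m]) for m in matchings
        )
        uniq, counts = np.unique(np.round(null.samples, 12), return_counts=True)
        np.testing.assert_allclose(sorted(uniq), expected, atol=1e-9)
        freqs = counts / null.n_reps
        assert np.all(np.abs(freqs - 1 / 3) < 0.03)

    def test_constant_metric_gives_degenerate_null(self):
        sym = symbolize(np.random.default_rng(3).random(100))
        inds = [sym] * 6  # identical individuals -> identical artificial pairs
        null = repair_null(inds, "srr", n_reps=50, seed=0)
        assert np.ptp(null.samples) == pytest.approx(0.0, abs=1e-15)
        assert null.observed == pytest.approx(null.samples[0])

    def test_seeded_determinism(self):
        inds = _individuals(8, seed=4)
        n1 = repair_null(inds, "te", n_reps=40, seed=9)
        n2 = repair_null(inds, "te", n_reps=40, seed=9)
        np.testing.assert_array_equal(n1.samples, n2.samples)

    def test_odd_count_rejected(self):
        with pytest.raises(PairingError):
            repair_null(_individuals(5), "mi", n_reps=5, seed=0)

    def test_te_null_has_both_directions(self):
        """Each artificial pair contributes two TE values, so the null mean
        averages 2N numbers — check against a manual recomputation."""
        inds = _individuals(4, seed=5)
        null = repair_null(inds, "te", n_reps=5, seed=11)
        from rhythmflow.information import transfer_entropy as te

        rng = np.random.default_rng(11)
        for r in range(5):
            pairs = rng.permutation(4).reshape(-1, 2)
            vals = []
            for i, j in pairs:
                vals.append(te(inds[i], inds[j]))
                vals.append(te(inds[j], inds[i]))
            assert null.samples[r] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_study_scale_smoke(self):
        """N=30 pairs at T=800 with a thousand reps completes quickly."""
        co = rf.generate_cohort(30, seed=8, n_sessions=1)
        _, codes = session_symbol_matrix(co, 1)
        syms = [SymbolSeries(codes=c, m=3) for c in codes]
        null = repair_null(syms, "mi", n_reps=200, seed=1)
        res = permutation_test(null)
        assert res.n_reps == 200
        assert 0 < res.p_value <= 1


class TestPermutationTest:
    def _null(self, samples, observed, sidedness):
        return NullDistribution(
            metric="mi" if sidedness == "one" else "srr",
            samples=np.asarray(samples, float),
            observed=observed,
            sidedness=sidedness,
        )

    def test_central_observed_not_significant(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=2000)
        res = permutation_test(self._null(s, float(np.median(s)), "two"))
        assert res.p_value > 0.9
        assert not res.significant

    def test_extreme_observed_minimal_p(self):
        s = np.random.default_rng(1).normal(size=999)
        res = permutation_test(self._null(s, s.max() + 10, "one"))
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.significant

    def test_sidedness_contract_at_97th_percentile(self):
        s = np.random.default_rng(2).normal(size=20_000)
        obs = float(np.percentile(s, 97))
        one = permutation_test(self._null(s, obs, "one"))
        two = permutation_test(self._null(s, obs, "two"))
        assert one.significant and not two.significant

    def test_add_one_estimator_never_zero(self):
        s = np.zeros(10)
        res = permutation_test(self._null(s, 5.0, "one"))
        assert res.p_value == pytest.approx(1 / 11)

    def test_empty_null_rejected(self):
        with pytest.raises(StateError):
            NullDistribution(metric="mi", samples=np.array([]), observed=0.0,
                             sidedness="one")


class TestSessionComparison:
    def _table(self, v1, v2):
        n = len(v1)
        pairs = pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)] * 2,
                "session": [1] * n + [2] * n,
                "srr": np.concatenate([v1, v2]),
                "entropy": 0.0,
                "mi": 0.0,
            }
        )
        return CohortTable(pairs=pairs, players=pd.DataFrame(
            columns=["pair_id", "player_id", "session", "te"]))

    def test_identical_sessions(self):
        v = np.random.default_rng(3).random(30)
        res = session_comparison(self._table(v, v.copy()), "srr")
        assert res.degenerate
        assert res.t == 0.0
        assert res.r == pytest.approx(1.0)

    def test_degrees_of_freedom_structure(self):
        rng = np.random.default_rng(4)
        v1, v2 = rng.random(30), rng.random(30)
        res = session_comparison(self._table(v1, v2), "srr")
        assert res.df_t == 29
        assert res.df_r == 28
        # t statistic of the correlation follows t = r sqrt(df/(1-r^2))
        assert res.t_r == pytest.approx(
            res.r * np.sqrt(28 / (1 - res.r**2)), abs=1e-12
        )

    def test_missing_session_rejected(self):
        v = np.random.default_rng(5).random(10)
        table = self._table(v, v)
        table.pairs = table.pairs[table.pairs["session"] == 1]
        with pytest.raises(PairingError):
            session_comparison(table, "srr")

    def test_power_matches_closed_form(self):
        """Monte-Carlo power of the paired t-test against the noncentral-t
        closed form, for a known shift and noise level."""
        n, delta, sigma = 40, 0.1, 0.25
        ncp = delta / (sigma / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        power_cf = 1 - stats.nct.cdf(tcrit, n - 1, ncp) + stats.nct.cdf(
            -tcrit, n - 1, ncp
        )
        rng = np.random.default_rng(6)
        hits = 0
        reps = 1200
        for _ in range(reps):
            diff = rng.normal(delta, sigma, n)
            v2 = rng.random(n)
            res = session_comparison(self._table(v2 + diff, v2), "srr")
            hits += res.p_t < 0.05
        mc = hits / reps
        assert mc == pytest.approx(power_cf, abs=3 * np.sqrt(power_cf * (1 - power_cf) / reps))


class TestCalibration:
    def test_type_i_error_of_mi_test(self):
        """Uncoupled cohorts: the one-sided re-pairing test should reject at
        its nominal 5% rate (checked at reduced replicate count)."""
        cfg = rf.DyadSimConfig(coupling_eps=0.0)
        link = rf.ExpertiseLink(slope=0.0, intercept=-10)  # eps ~ 0
        rejections = 0
        n_cohorts = 60
        for k in range(n_cohorts):
            co = rf.generate_cohort(
                10, expertise_model=link, seed=5000 + k, config=cfg, n_sessions=1
            )
            _, codes = session_symbol_matrix(co, 1)
            syms = [SymbolSeries(codes=c, m=3) for c in codes]
            null = repair_null(syms, "mi", n_reps=199, seed=k)
            rejections += permutation_test(null).significant
        rate = rejections / n_cohorts
        assert rate < 0.18  # loose 3-sigma band around 5% at 60 cohorts

    def test_power_of_te_test_under_coupling(self):
        """Coupled cohorts (eps=0.5): the one-sided TE test rejects nearly
        always even at small N and few reps."""
        cfg = rf.DyadSimConfig(coupling_eps=0.5)
        link = rf.ExpertiseLink(slope=0.0, intercept=0.0)  # eps = 0.5
        hits = 0
        n_cohorts = 10
        for k in range(n_cohorts):
            co = rf.generate_cohort(
                10, expertise_model=link, seed=6000 + k, config=cfg, n_sessions=1
            )
            _, codes = session_symbol_matrix(co, 1)
            syms = [SymbolSeries(codes=c, m=3) for c in codes]
            null = repair_null(syms, "te", n_reps=199, seed=k)
            hits += permutation_test(null).significant
        assert hits >= 9


class TestCohortTable:
    def test_row_structure(self, small_cohort, small_cohort_table):
        table = small_cohort_table
        n_pairs = len(small_cohort.pair_ids)
        assert len(table.pairs) == n_pairs * 2
        assert len(table.players) == n_pairs * 2 * 2
        assert {"sum_collab", "diff_collab", "sum_years", "diff_years"} <= set(
            table.pairs.columns
        )
        assert {"focal_collab", "partner_collab"} <= set(table.players.columns)

    def test_te_received_orientation(self, small_cohort, small_cohort_table):
        """The player row holds TE from partner to focal player."""
        from rhythmflow.information import transfer_entropy

        pair_id = small_cohort.pair_ids[0]
        dyad = small_cohort.dyads[(pair_id, 1)]
        sa, sb = symbolize(dyad.series_a), symbolize(dyad.series_b)
        row = small_cohort_table.players.query(
            "pair_id == @pair_id and session == 1 and player_id == 'a'"
        ).iloc[0]
        assert row["te"] == pytest.approx(transfer_entropy(sb, sa))
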