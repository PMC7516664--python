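import math

import numpy as np
import pytest

import rhythmflow as rf
from rhythmflow.errors import AlignmentError, LengthError
from rhythmflow.information import (
    joint_recurrence_profile,
    mutual_information,
    pair_series,
    te_tuple_series,
    transfer_entropy,
)
from rhythmflow.symbolic import SymbolSeries, srr_profile, symbolize

from _oracles import (
    oracle_mi_joint_marginal,
    oracle_mi_literal,
    oracle_profile,
    oracle_te_joint_marginal,
    oracle_te_literal,
)


def _sym(codes, m=3):
    return SymbolSeries(codes=np.asarray(codes), m=m)


class TestJointProfile:
    def test_identical_components_collapse_to_diagonal(self, rng):
        x = symbolize(rng.random(60))
        joint = joint_recurrence_profile(pair_series(x, x))
        uni = srr_profile(x)
        assert joint.srr == pytest.approx(uni.srr, abs=1e-15)
        assert joint.entropy == pytest.approx(uni.entropy, abs=1e-12)

    def test_constant_component_reduces_to_other(self, rng):
        y = symbolize(rng.random(60))
        x = _sym(np.zeros(len(y), dtype=int))
        joint = joint_recurrence_profile(pair_series(x, y))
        uni = srr_profile(y)
        assert joint.srr == pytest.approx(uni.srr, abs=1e-15)
        assert joint.entropy == pytest.approx(uni.entropy, abs=1e-12)

    def test_matches_tuple_double_loop_oracle(self, rng):
        x = symbolize(rng.random(100))
        y = symbolize(rng.random(100))
        joint = joint_recurrence_profile(pair_series(x, y))
        tuples = list(zip(x.patterns, y.patterns))
        _, srr, _, entropy = oracle_profile(tuples)
        assert joint.srr == pytest.approx(srr, abs=1e-12)
        assert joint.entropy == pytest.approx(entropy, abs=1e-12)

    def test_misaligned_lengths_raise(self, rng):
        x = symbolize(rng.random(50))
        y = symbolize(rng.random(40))
        with pytest.raises(AlignmentError):
            pair_series(x, y)


class TestMutualInformation:
    @pytest.mark.parametrize("mode", ["literal", "joint-marginal"])
    def test_self_information_equals_entropy(self, rng, mode):
        x = symbolize(rng.random(100))
        h = srr_profile(x).entropy
        assert mutual_information(x, x, mode=mode) == pytest.approx(h, abs=1e-12)

    @pytest.mark.parametrize("mode", ["literal", "joint-marginal"])
    def test_symmetry(self, rng, mode):
        x = symbolize(rng.random(80))
        y = symbolize(rng.random(80))
        assert mutual_information(x, y, mode=mode) == pytest.approx(
            mutual_information(y, x, mode=mode), abs=1e-12
        )

    def test_hand_worked_small_pair(self):
        """T̄=8 symbol pair with counts worked through the defining equations.

        x = (0,0,1,1,0,0,1,2), y = (2,2,2,3,3,3,2,2):
        symbol counts x: {0:4, 1:3, 2:1}, weights c(c-1) = (12, 6, 0);
        y: {2:5, 3:3}, weights (20, 6); pair counts: (0,2)x2, (1,2)x2,
        (0,3)x2, (1,3)x1, (2,2)x1, weights (2, 2, 2) => H(x,y) = log2 3.
        """
        x = _sym([0, 0, 1, 1, 0, 0, 1, 2])
        y = _sym([2, 2, 2, 3, 3, 3, 2, 2])
        hx = -(12 / 18) * math.log2(12 / 18) - (6 / 18) * math.log2(6 / 18)
        hy = -(20 / 26) * math.log2(20 / 26) - (6 / 26) * math.log2(6 / 26)
        hxy = math.log2(3)
        expected = hx + hy - hxy
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(
            oracle_mi_literal(x.patterns, y.patterns), abs=1e-12
        )

    @pytest.mark.parametrize("mode", ["literal", "joint-marginal"])
    def test_matches_oracle_on_random_instances(self, rng, mode):
        oracle = {
            "literal": oracle_mi_literal,
            "joint-marginal": oracle_mi_joint_marginal,
        }[mode]
        for _ in range(10):
            x = symbolize(rng.random(60))
            y = symbolize(rng.random(60))
            assert mutual_information(x, y, mode=mode) == pytest.approx(
                oracle(x.patterns, y.patterns), abs=1e-10
            )

    def test_joint_marginal_nonnegative(self, rng):
        for _ in range(20):
            x = symbolize(rng.random(40))
            y = symbolize(rng.random(40))
            assert mutual_information(x, y, mode="joint-marginal") >= -1e-12

    def test_independent_iid_mi_is_small(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = symbolize(r.random(10_000))
            y = symbolize(r.random(10_000))
            vals.append(mutual_information(x, y, mode="joint-marginal"))
        assert np.mean(vals) < 0.02

    def test_undefined_when_component_recurrence_free(self):
        x = _sym(np.arange(6))
        y = _sym(np.zeros(6, dtype=int))
        assert math.isnan(mutual_information(x, y))


class TestTransferEntropy:
    def test_deterministic_copy_limit(self, rng):
        """x_{t+1} := y_t exactly => TE(y->x) = H(x_{t+1}|x_t)."""
        y = rng.random(400)
        x = np.empty_like(y)
        x[1:] = y[:-1]
        x[0] = rng.random()
        sx, sy = symbolize(x), symbolize(y)
        te = transfer_entropy(sy, sx)
        # H(x+|x) from its own tuple profile on the aligned length
        x1, x0 = sx.codes[1:], sx.codes[:-1]
        from rhythmflow.symbolic import recurrence_entropy_from_counts

        h_pair = recurrence_entropy_from_counts(
            np.bincount(x1 * 6 + x0, minlength=36)
        )
        h_x0 = recurrence_entropy_from_counts(np.bincount(x0, minlength=6))
        assert te == pytest.approx(h_pair - h_x0, abs=1e-12)
        # reverse direction carries no signal beyond bias
        assert transfer_entropy(sx, sy) < 0.05

    @pytest.mark.parametrize("mode", ["literal", "joint-marginal"])
    def test_matches_oracle_on_random_instances(self, rng, mode):
        oracle = {
            "literal": oracle_te_literal,
            "joint-marginal": oracle_te_joint_marginal,
        }[mode]
        for _ in range(10):
            src = symbolize(rng.random(60))
            tgt = symbolize(rng.random(60))
            assert transfer_entropy(src, tgt, mode=mode) == pytest.approx(
                oracle(src.patterns, tgt.patterns), abs=1e-10
            )

    def test_joint_marginal_conditioning_reduces_entropy(self, rng):
        """H(x+|x,y) <= H(x+|x) when all terms share one tuple distribution."""
        for _ in range(20):
            src = symbolize(rng.random(50))
            tgt = symbolize(rng.random(50))
            assert transfer_entropy(src, tgt, mode="joint-marginal") >= -1e-9

    def test_directionality_recovery_on_coupled_dyads(self):
        wins = 0
        n = 30
        for seed in range(n):
            dyad = rf.generate_dyad(
                rf.DyadSimConfig(seed=900 + seed, coupling_eps=0.75)
            )
            sa = symbolize(dyad.series_a)
            sb = symbolize(dyad.series_b)
            if transfer_entropy(sa, sb) > transfer_entropy(sb, sa):
                wins += 1
        assert wins >= 0.9 * n

    def test_independent_iid_te_is_small(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = symbolize(r.random(10_000))
            y = symbolize(r.random(10_000))
            vals.append(transfer_entropy(x, y))
            vals.append(transfer_entropy(y, x))
        assert abs(np.mean(vals)) < 0.02

    def test_lag_validation(self, rng):
        x = symbolize(rng.random(10))
        with pytest.raises(ValueError):
            te_tuple_series(x, x, lag=0)
        with pytest.raises(LengthError):
            transfer_entropy(x, x, lag=8)


class TestDyadMetrics:
    def test_bundles_are_consistent_with_parts(self, rng):
        a, b = rng.random(200), rng.random(200)
        dm = rf.dyad_metrics(a, b, pair_id="p0", session=1)
        sa, sb = symbolize(a), symbolize(b)
        assert dm.mi == pytest.approx(mutual_information(sa, sb))
        assert dm.te_a_to_b == pytest.approx(transfer_entropy(sa, sb))
        assert dm.te_b_to_a == pytest.approx(transfer_entropy(sb, sa))
        joint = joint_recurrence_profile(pair_series(sa, sb))
        assert dm.srr == pytest.approx(joint.srr)
        assert dm.entropy == pytest.approx(joint.entropy)
        assert dm.pair_id == "p0" and dm.session == 1
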