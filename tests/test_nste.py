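from math import factorial, log2

import numpy as np
import pytest

from dyadcoord.errors import InputError, ParameterError
from dyadcoord.kinematics import SpeedSeries
from dyadcoord.nste import (
    NSTEParams,
    SymbolSeries,
    asymmetry,
    nste,
    nste_windowed,
    ordinal_symbolize,
    smooth_nonoverlapping,
    ste,
)
from dyadcoord.nste import _ste_from_counts, _triplet_counts
from dyadcoord.pose_io import CANONICAL_MARKERS
from dyadcoord.synth import EpisodeSpec, simulate_dyad


class TestOrdinalSymbolize:
    def test_strictly_increasing_maps_to_identity_symbol(self):
        s = ordinal_symbolize(np.arange(20.0), m=3, tau=2)
        np.testing.assert_array_equal(s.symbols, 0)

    def test_worked_pattern(self):
        # (4,1,3): ranks (2,0,1); permutations of (0,1,2) in lexicographic
        # order put (2,0,1) at index 4
        s = ordinal_symbolize(np.array([4.0, 1.0, 3.0]), m=3, tau=1)
        assert s.symbols.tolist() == [4]

    def test_all_six_patterns_enumerated(self):
        expected = {
            (1.0, 2.0, 3.0): 0,  # ranks 012
            (1.0, 3.0, 2.0): 1,  # ranks 021
            (2.0, 1.0, 3.0): 2,  # ranks 102
            (3.0, 1.0, 2.0): 4,  # ranks 201
            (2.0, 3.0, 1.0): 3,  # ranks 120
            (3.0, 2.0, 1.0): 5,  # ranks 210
        }
        for vec, symbol in expected.items():
            assert ordinal_symbolize(np.array(vec), 3, 1).symbols[0] == symbol

    def test_length_contract(self, rng):
        n, m, tau = 100, 3, 7
        s = ordinal_symbolize(rng.normal(size=n), m, tau)
        assert len(s) == n - (m - 1) * tau

    def test_ties_broken_by_earlier_position(self):
        s = ordinal_symbolize(np.array([1.0, 1.0, 0.0]), 3, 1)
        # ties: first sample ranks below the equal second -> ranks (1,2,0)
        t = ordinal_symbolize(np.array([2.0, 3.0, 1.0]), 3, 1)
        assert s.symbols[0] == t.symbols[0]

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=300)
        a = ordinal_symbolize(x, 3, 5).symbols
        b = ordinal_symbolize(np.exp(x), 3, 5).symbols
        np.testing.assert_array_equal(a, b)

    def test_too_short_segment_rejected(self):
        with pytest.raises(InputError):
            ordinal_symbolize(np.zeros(4), m=3, tau=2)


class TestSte:
    def test_independent_product_table_gives_zero(self):
        # exact product distribution: counts factorize completely
        k = 6
        c3 = np.ones((k, k, k))
        assert _ste_from_counts(c3) == 0.0

    def test_deterministic_copy_gives_log2_6(self):
        # y_future = x_present exactly, x uniform, y_present independent
        k = 6
        c3 = np.zeros((k, k, k))
        for yp in range(k):
            for xp in range(k):
                c3[xp, yp, xp] = 1.0
        assert _ste_from_counts(c3) == pytest.approx(log2(6), abs=1e-12)

    def test_matches_triple_loop_brute_force(self, rng):
        k = 6
        for _ in range(5):
            src = SymbolSeries(rng.integers(0, k, 200), m=3, tau=1)
            tgt = SymbolSeries(rng.integers(0, k, 200), m=3, tau=1)
            delta = int(rng.integers(1, 5))
            got = ste(src, tgt, delta)
            # brute force over the full count table
            yf, yp, xp = (
                tgt.symbols[delta:],
                tgt.symbols[:-delta],
                src.symbols[:-delta],
            )
            n = len(yf)
            total = 0.0
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        cnt = np.sum((yf == a) & (yp == b) & (xp == c))
                        if cnt == 0:
                            continue
                        p_joint = cnt / n
                        p_cond_src = cnt / np.sum((yp == b) & (xp == c))
                        p_cond = np.sum((yf == a) & (yp == b)) / np.sum(yp == b)
                        total += p_joint * log2(p_cond_src / p_cond)
            assert got == pytest.approx(total, abs=1e-12)

    def test_nonnegative_on_random_symbols(self, rng):
        for _ in range(20):
            src = SymbolSeries(rng.integers(0, 6, 60), m=3, tau=1)
            tgt = SymbolSeries(rng.integers(0, 6, 60), m=3, tau=1)
            assert ste(src, tgt, 2) >= 0.0

    def test_constant_target_gives_zero(self):
        src = SymbolSeries(np.arange(50) % 6, m=3, tau=1)
        tgt = SymbolSeries(np.zeros(50, dtype=np.int64), m=3, tau=1)
        assert ste(src, tgt, 1) == 0.0


class TestNste:
    def test_constant_target_convention(self):
        src = np.sin(np.arange(120.0))
        tgt = np.zeros(120)
        assert nste(src, tgt, m=3, tau=9, rng=0) == 0.0

    def test_bounded(self, rng):
        for _ in range(20):
            v = nste(rng.normal(size=120), rng.normal(size=120), m=3, tau=9, rng=rng)
            assert -1.0 <= v <= 1.0

    def test_null_mean_near_zero(self):
        vals = []
        for i in range(50):
            r = np.random.default_rng(500 + i)
            vals.append(
                nste(r.normal(size=120), r.normal(size=120), m=3, tau=9, rng=r)
            )
        assert abs(np.mean(vals)) <= 0.05

    def test_delayed_copy_prefers_true_direction(self):
        wins = 0
        trials = 30
        for i in range(trials):
            r = np.random.default_rng(900 + i)
            n, delta = 240, 9
            src = np.cumsum(r.normal(size=n + delta))
            tgt = src[:-delta] + 0.05 * r.normal(size=n)
            src = src[delta:]
            fwd = nste(src, tgt, m=3, tau=delta, rng=np.random.default_rng(1))
            rev = nste(tgt, src, m=3, tau=delta, rng=np.random.default_rng(1))
            wins += fwd > rev
        assert wins >= 0.9 * trials


class TestAsymmetry:
    def test_equal_flows_balance(self):
        assert asymmetry(0.2, 0.2) == 0.0

    def test_worked_ratio(self):
        assert asymmetry(0.3, 0.1) == pytest.approx(0.5)

    def test_antisymmetric_and_bounded(self, rng):
        for _ in range(50):
            a, b = rng.uniform(-0.5, 1.0, size=2)
            v = asymmetry(a, b)
            assert v == pytest.approx(-asymmetry(b, a))
            assert -1.0 <= v <= 1.0

    def test_zero_over_zero(self):
        assert asymmetry(0.0, -0.3) == 0.0


class TestNsteWindowed:
    def test_window_count_arithmetic(self):
        # a 15-min session at 60 Hz: floor((900 - 2) / 0.5) + 1 = 1797
        n = 54_000 - 1
        duration = (n + 1) / 60.0
        assert int(np.floor((duration - 2.0) / 0.5)) + 1 == 1797

    def test_symmetric_inputs_give_symmetric_nste(self, rng):
        v = np.abs(rng.normal(size=1200)) + 0.1
        speeds = {
            m: SpeedSeries(fps=60.0, values=v.copy(), marker=m)
            for m in CANONICAL_MARKERS
        }
        res = nste_windowed(speeds, NSTEParams(tau_range=(9,), seed=0))
        # B is a copy of A: directional difference stays within null spread
        assert np.nanmean(np.abs(res.nste_ab - res.nste_ba)) < 0.15

    def test_leader_recovered_in_coupled_episode(self):
        correct = total = 0
        for seed in range(3):
            sess = simulate_dyad(
                [EpisodeSpec(0, 20, "coupled", leader="B", lag=150.0, coupling=0.9)],
                duration=20.0,
                seed=seed,
            )
            speeds = {
                m: SpeedSeries(fps=60.0, values=sess.latent_speeds[m], marker=m)
                for m in CANONICAL_MARKERS
            }
            res = nste_windowed(speeds, NSTEParams(seed=seed))
            correct += int((res.asymmetry < 0).sum())  # B leads -> negative
            total += len(res)
        assert correct / total >= 0.8

    def test_too_short_window_parameters_rejected(self, noise_speeds):
        with pytest.raises(ParameterError):
            nste_windowed(noise_speeds, NSTEParams(window=0.5))


class TestSmoothNonoverlapping:
    def test_constant_stays_constant(self):
        t = np.arange(0, 30, 0.5)
        centers, means = smooth_nonoverlapping(t, np.full(t.size, 2.0))
        np.testing.assert_allclose(means, 2.0)

    def test_two_bins_of_three(self):
        t = np.arange(6.0)  # six samples, 1 s apart -> two 3-s bins
        centers, means = smooth_nonoverlapping(t, np.arange(1.0, 7.0))
        np.testing.assert_allclose(means, [2.0, 5.0])
        np.testing.assert_allclose(centers, [1.5, 4.5])

    def test_bin_count_floor(self):
        t = np.arange(0, 10, 0.5)  # spans 10 s of samples
        centers, _ = smooth_nonoverlapping(t, np.zeros(t.size))
        assert centers.size == 3  # floor(10 / 3)
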