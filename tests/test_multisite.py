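"""Boltzmann-sum protonation engine versus literal enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkashift.multisite import (
    LN10,
    R_GAS_KJ,
    AmbiguousTransitionWarning,
    NoTransitionError,
    ShiftModel,
    Site,
    SiteSystem,
    apparent_pka,
    microstate_energy,
    microstates,
    predict_shift,
    predict_shifts,
    protonation_fraction,
    protonation_fractions,
    state_energies,
)

# ---------------------------------------------------------------------------
# independent oracle: literal per-microstate loops, no vectorisation shared
# with the implementation under test
# ---------------------------------------------------------------------------


def oracle_energy(pkas, W, charges, temperature, state, pH):
    rt = R_GAS_KJ * temperature
    e = 0.0
    for i, x in enumerate(state):
        if x == 1:
            e += LN10 * rt * (pH - pkas[i])
    n = len(state)
    for i in range(n):
        for j in range(i + 1, n):
            qi = charges[i] if state[i] == 0 else 0.0
            qj = charges[j] if state[j] == 0 else 0.0
            e += W[i][j] * qi * qj
    return e


def oracle_fraction(pkas, W, charges, temperature, site, pH):
    rt = R_GAS_KJ * temperature
    num = den = 0.0
    for state in itertools.product((0, 1), repeat=len(pkas)):
        g = oracle_energy(pkas, W, charges, temperature, state, pH)
        b = math.exp(-g / rt)
        den += b
        if state[site] == 1:
            num += b
    return num / den


def make_system(pkas, w=None, temperature=298.0):
    n = len(pkas)
    W = np.zeros((n, n))
    if w is not None:
        W[:] = w
        np.fill_diagonal(W, 0.0)
    return SiteSystem(tuple(Site(f"S{i}", p) for i, p in enumerate(pkas)), W, temperature)


class TestMicrostateEnergy:
    def test_single_protonated_site_at_its_pka_has_zero_energy(self):
        s = make_system([4.0])
        assert microstate_energy(s, [1], 4.0) == pytest.approx(0.0, abs=1e-14)

    def test_zero_coupling_energy_is_additive_over_sites(self):
        s2 = make_system([3.5, 4.8])
        a = make_system([3.5])
        b = make_system([4.8])
        for state in itertools.product((0, 1), repeat=2):
            e = microstate_energy(s2, state, 5.2)
            ea = microstate_energy(a, state[:1], 5.2)
            eb = microstate_energy(b, state[1:], 5.2)
            assert e == pytest.approx(ea + eb, abs=1e-12)

    def test_two_deprotonated_acids_pay_the_pairwise_repulsion(self):
        # a measured carboxylate/lysine pair interaction of 3.6 kJ/mol sets
        # the physically relevant magnitude; two anions give q_i*q_j = +1
        s = make_system([4.0, 4.0], w=3.6)
        both_deprot = microstate_energy(s, [0, 0], 4.0)
        assert both_deprot == pytest.approx(3.6, abs=1e-12)

    def test_dimension_mismatch_is_rejected(self):
        s = make_system([4.0, 4.0])
        with pytest.raises(ValueError, match="sites"):
            microstate_energy(s, [1], 4.0)

    @pytest.mark.parametrize("pH", [1.0, 3.7, 7.2])
    def test_energy_matches_literal_oracle(self, pH):
        pkas, w = [3.2, 4.6, 5.1], 2.5
        s = make_system(pkas, w=w)
        W = s.W.tolist()
        charges = [-1.0] * 3
        for state in itertools.product((0, 1), repeat=3):
            assert microstate_energy(s, state, pH) == pytest.approx(
                oracle_energy(pkas, W, charges, 298.0, state, pH), abs=1e-10
            )


class TestProtonationFraction:
    def test_half_protonated_at_intrinsic_pka(self):
        s = make_system([4.0])
        assert protonation_fraction(s, 0, 4.0) == pytest.approx(0.5, abs=1e-12)

    def test_single_site_closed_form(self):
        s = make_system([4.0])
        assert protonation_fraction(s, 0, 6.0) == pytest.approx(1 / 101, rel=1e-12)

    @pytest.mark.parametrize("w", [0.0, 2.0, 5.0, -3.0])
    @pytest.mark.parametrize("pH", np.linspace(1.0, 9.0, 7).tolist())
    def test_matches_enumeration_oracle_two_sites(self, w, pH):
        pkas = [4.0, 4.0]
        s = make_system(pkas, w=w)
        for i in range(2):
            assert protonation_fraction(s, i, pH) == pytest.approx(
                oracle_fraction(pkas, s.W.tolist(), [-1, -1], 298.0, i, pH), abs=1e-10
            )

    def test_matches_enumeration_oracle_four_sites(self):
        pkas = [2.8, 3.9, 4.4, 5.6]
        rng = np.random.default_rng(0)
        W = rng.uniform(-3, 3, (4, 4))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        s = SiteSystem(tuple(Site(f"S{i}", p) for i, p in enumerate(pkas)), W, 310.0)
        for pH in (2.0, 4.1, 6.3):
            for i in range(4):
                assert protonation_fraction(s, i, pH) == pytest.approx(
                    oracle_fraction(pkas, W.tolist(), [-1] * 4, 310.0, i, pH),
                    abs=1e-10,
                )

    def test_uncoupled_system_reduces_to_independent_hh_curves(self):
        pkas = [3.1, 4.2, 5.3]
        s = make_system(pkas)
        ph = np.linspace(0, 14, 57)
        f = protonation_fractions(s, ph)
        for i, pka in enumerate(pkas):
            expected = 1.0 / (1.0 + 10.0 ** (ph - pka))
            assert np.allclose(f[i], expected, atol=1e-10)

    def test_probabilities_normalised_and_fractions_bounded(self):
        s = make_system([3.0, 4.5, 6.0], w=4.0)
        ph = np.linspace(0, 14, 141)
        E = state_energies(s, ph)
        p = np.exp(-(E - E.min(axis=0)) / s.rt)
        p /= p.sum(axis=0)
        assert np.all(np.abs(p.sum(axis=0) - 1.0) < 1e-12)
        f = protonation_fractions(s, ph)
        assert np.all(f >= 0) and np.all(f <= 1)

    def test_monotone_decreasing_without_coupling(self):
        s = make_system([3.0, 5.0])
        ph = np.linspace(0, 14, 200)
        f = protonation_fractions(s, ph)
        assert np.all(np.diff(f, axis=1) < 0)

    def test_site_permutation_permutes_outputs(self):
        pkas = [3.3, 4.4, 5.5]
        W = np.array([[0, 1.0, 2.0], [1.0, 0, 0.5], [2.0, 0.5, 0]])
        s = SiteSystem(tuple(Site(f"S{i}", p) for i, p in enumerate(pkas)), W)
        perm = [2, 0, 1]
        sp = SiteSystem(
            tuple(Site(f"S{i}", pkas[j]) for i, j in enumerate(perm)),
            W[np.ix_(perm, perm)],
        )
        ph = np.linspace(1, 9, 17)
        f = protonation_fractions(s, ph)
        fp = protonation_fractions(sp, ph)
        for i, j in enumerate(perm):
            assert np.allclose(fp[i], f[j], atol=1e-12)

    def test_refuses_oversized_enumeration(self):
        with pytest.raises(ValueError, match="capped"):
            make_system([4.0] * 21)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        pka=st.floats(1.0, 9.0),
        w=st.floats(-5.0, 8.0),
        pH=st.floats(0.0, 14.0),
    )
    def test_two_site_fraction_always_matches_oracle(self, pka, w, pH):
        s = make_system([pka, pka + 1.0], w=w)
        for i in range(2):
            assert protonation_fraction(s, i, pH) == pytest.approx(
                oracle_fraction([pka, pka + 1.0], s.W.tolist(), [-1, -1], 298.0, i, pH),
                abs=1e-10,
            )


class TestApparentPka:
    def test_identity_in_uncoupled_limit(self):
        s = make_system([3.20])
        assert apparent_pka(s, 0) == pytest.approx(3.20, abs=1e-6)

    def test_uncoupled_multisite_returns_each_intrinsic_value(self):
        pkas = [2.7, 4.1, 5.9]
        s = make_system(pkas)
        for i, pka in enumerate(pkas):
            assert apparent_pka(s, i) == pytest.approx(pka, abs=1e-6)

    def test_repulsive_coupling_splits_apparent_pkas(self):
        # two acids straddling pH 4 with strong repulsion: the upper site's
        # half-protonation point moves further up, the gap widens
        s = make_system([3.8, 4.2], w=6.0)
        lo = apparent_pka(s, 0)
        hi = apparent_pka(s, 1)
        assert hi - lo > 4.2 - 3.8
        # verify against a dense numeric root of the 4-state oracle
        for i, val in ((0, lo), (1, hi)):
            g = lambda p: oracle_fraction([3.8, 4.2], s.W.tolist(), [-1, -1], 298.0, i, p) - 0.5
            from scipy.optimize import brentq

            assert val == pytest.approx(brentq(g, 0, 14, xtol=1e-9), abs=1e-5)

    def test_no_crossing_raises(self):
        s = make_system([4.0])
        with pytest.raises(NoTransitionError):
            apparent_pka(s, 0, window=(9.0, 14.0))


class TestPredictShift:
    def test_single_site_reduces_to_hh_form(self):
        dA, dB, pka = 179.0, 183.5, 4.17
        s = make_system([pka])
        sm = ShiftModel([dA], [[dB - dA]])
        ph = np.linspace(0, 14, 141)
        pred = predict_shifts(s, sm, ph)[0]
        r = 10.0 ** (ph - pka)
        assert np.allclose(pred, (dA + dB * r) / (1 + r), atol=1e-10)

    def test_zero_amplitudes_give_flat_baseline(self):
        s = make_system([4.0, 5.0])
        sm = ShiftModel([180.0, 181.0], np.zeros((2, 2)))
        ph = np.linspace(1, 9, 9)
        pred = predict_shifts(s, sm, ph)
        assert np.allclose(pred[0], 180.0) and np.allclose(pred[1], 181.0)

    def test_cross_amplitudes_make_biphasic_curves(self):
        # the minor transition of one reporter sits at the other site's
        # apparent pKa: the derivative has two local maxima in magnitude
        s = make_system([3.0, 5.5], w=2.0)
        sm = ShiftModel([179.0, 179.5], [[3.0, 0.8], [0.7, 3.2]])
        ph = np.linspace(1, 9, 400)
        d = predict_shifts(s, sm, ph)[0]
        slope = np.diff(d)
        peaks = [
            k
            for k in range(1, len(slope) - 1)
            if slope[k] > slope[k - 1] and slope[k] > slope[k + 1] and slope[k] > 1e-4
        ]
        assert len(peaks) == 2
        app0, app1 = apparent_pka(s, 0), apparent_pka(s, 1)
        peak_phs = sorted(ph[k] for k in peaks)
        assert peak_phs[0] == pytest.approx(min(app0, app1), abs=0.15)
        assert peak_phs[1] == pytest.approx(max(app0, app1), abs=0.15)

    def test_dimension_mismatch_rejected(self):
        s = make_system([4.0])
        sm = ShiftModel([179.0], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            predict_shift(s, sm, 0, 4.0)


class TestSerialization:
    def test_config_round_trip(self):
        s = make_system([3.2, 4.6], w=3.6, temperature=333.0)
        text = s.to_config_text()
        back = SiteSystem.from_config_text(text)
        assert back.labels == s.labels
        assert np.allclose(back.pka_int, s.pka_int)
        assert np.allclose(back.W, s.W)
        assert back.temperature == s.temperature

    def test_invalid_w_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SiteSystem((Site("a", 4.0), Site("b", 4.0)), np.array([[0.0, 1.0], [2.0, 0.0]]))
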