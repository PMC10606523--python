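import numpy as np
import pytest
from hypothesis import given, strategies as st

from pkagrid.titration import (
    MCSettings,
    MicrostateModel,
    TitrationError,
    henderson_hasselbalch,
    microstate_energy,
    pka_from_curve,
    titrate_exact,
    titrate_mc,
)


def model(pkas, acids, W=None, ph=None):
    n = len(pkas)
    kwargs = {} if ph is None else {"ph_grid": np.asarray(ph)}
    return MicrostateModel(
        site_ids=[f"s{i}" for i in range(n)],
        intrinsic_pka=np.asarray(pkas, dtype=float),
        is_acid=np.asarray(acids, dtype=bool),
        W=np.zeros((n, n)) if W is None else np.asarray(W, dtype=float),
        **kwargs,
    )


def random_model(seed, n, wmax=0.5, acid_prob=0.5):
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            W[i, j] = W[j, i] = rng.uniform(0, wmax)
    return model(rng.uniform(3.0, 10.0, n), rng.random(n) < acid_prob, W)


class TestMicrostateEnergy:
    def test_two_acid_hand_enumeration(self):
        # acids 4.0/5.0, W=2.0, pH 5.0; dq = x for acids
        m = model([4.0, 5.0], [True, True], [[0, 2.0], [2.0, 0]])
        expected = {(0, 0): 0.0, (1, 0): 1.0, (0, 1): 0.0, (1, 1): 3.0}
        for state, e in expected.items():
            assert microstate_energy(state, 5.0, m) == pytest.approx(e)

    def test_reference_state_has_no_pair_energy(self):
        m = model([4.0, 10.4], [True, False], [[0, 1.5], [1.5, 0]])
        ref = tuple(m.reference_state())
        e_ref = microstate_energy(ref, 7.0, m)
        e_ref_noW = microstate_energy(ref, 7.0, model([4.0, 10.4], [True, False]))
        assert e_ref == pytest.approx(e_ref_noW)

    def test_single_site_states_equal_at_intrinsic_pka(self):
        m = model([6.0], [True])
        assert microstate_energy([1], 6.0, m) == pytest.approx(microstate_energy([0], 6.0, m))

    def test_length_mismatch_rejected(self):
        with pytest.raises(TitrationError):
            microstate_energy([1, 0], 7.0, model([6.0], [True]))


class TestExact:
    def test_single_acid_is_henderson_hasselbalch(self):
        m = model([6.0], [True])
        r = titrate_exact(m)
        np.testing.assert_allclose(
            r.fractions[:, 0], henderson_hasselbalch(m.ph_grid, 6.0), atol=1e-12
        )
        assert r.pka(0) == pytest.approx(6.0, abs=1e-9)

    def test_base_curve_equals_acid_curve_without_coupling(self):
        # protonation fraction follows the same law for acids and bases
        ra = titrate_exact(model([7.0], [True]))
        rb = titrate_exact(model([7.0], [False]))
        np.testing.assert_allclose(ra.fractions, rb.fractions, atol=1e-12)

    def test_noninteracting_sites_factorize(self):
        m2 = model([5.0, 8.0], [True, False])
        r2 = titrate_exact(m2)
        for i, pk in enumerate([5.0, 8.0]):
            np.testing.assert_allclose(
                r2.fractions[:, i], henderson_hasselbalch(m2.ph_grid, pk), atol=1e-12
            )

    def test_symmetric_coupled_acids_share_one_curve(self):
        m = model([4.0, 4.0], [True, True], [[0, 2.0], [2.0, 0]])
        r = titrate_exact(m)
        np.testing.assert_allclose(r.fractions[:, 0], r.fractions[:, 1], atol=1e-12)
        # repulsive coupling between deprotonated forms spreads the curve
        single = titrate_exact(model([4.0], [True]))
        assert r.fractions[:, 0].max() > 0.99 and r.fractions[:, 0].min() < 0.01
        assert not np.allclose(r.fractions[:, 0], single.fractions[:, 0], atol=0.01)

    def test_state_probabilities_are_normalized(self):
        # fractions bounded by construction of a normalized distribution
        m = random_model(7, 6, wmax=1.5)
        r = titrate_exact(m)
        assert np.all(r.fractions >= -1e-12) and np.all(r.fractions <= 1 + 1e-12)

    def test_site_limit_enforced(self):
        with pytest.raises(TitrationError, match="titrate_mc"):
            titrate_exact(random_model(0, 21))

    @given(st.integers(0, 1000))
    def test_permuting_sites_permutes_outputs(self, seed):
        m = random_model(seed, 4, wmax=1.0)
        perm = np.random.default_rng(seed).permutation(4)
        mp = MicrostateModel(
            site_ids=[m.site_ids[i] for i in perm],
            intrinsic_pka=m.intrinsic_pka[perm],
            is_acid=m.is_acid[perm],
            W=m.W[np.ix_(perm, perm)],
            ph_grid=m.ph_grid,
        )
        r, rp = titrate_exact(m), titrate_exact(mp)
        np.testing.assert_allclose(r.fractions[:, perm], rp.fractions, atol=1e-10)


class TestMonteCarlo:
    FAST = MCSettings(burn_in=200, scans=5000)

    def test_uncoupled_sites_reproduce_closed_form(self):
        m = model([4.5, 9.0, 6.2], [True, False, True])
        r = titrate_mc(m, seed=1, settings=self.FAST)
        for i, pk in enumerate([4.5, 9.0, 6.2]):
            np.testing.assert_allclose(
                r.fractions[:, i], henderson_hasselbalch(m.ph_grid, pk), atol=1e-9
            )

    def test_matches_exact_enumeration(self):
        m = random_model(11, 8, wmax=0.5)
        ex = titrate_exact(m)
        mc = titrate_mc(m, seed=3, settings=MCSettings(burn_in=500, scans=20000))
        assert np.abs(mc.fractions - ex.fractions).max() <= 0.01

    def test_same_seed_reproduces_bitwise(self):
        m = random_model(5, 5, wmax=1.0)
        r1 = titrate_mc(m, seed=42, settings=self.FAST)
        r2 = titrate_mc(m, seed=42, settings=self.FAST)
        np.testing.assert_array_equal(r1.fractions, r2.fractions)

    def test_two_seeds_agree_within_pooled_error(self):
        m = random_model(5, 5, wmax=1.0)
        r1 = titrate_mc(m, seed=1, settings=self.FAST)
        r2 = titrate_mc(m, seed=2, settings=self.FAST)
        pooled = np.sqrt(r1.mc_error**2 + r2.mc_error**2) + 1e-12
        assert np.abs(r1.fractions - r2.fractions).max() <= np.maximum(3 * pooled, 1e-3).max()

    def test_strongly_coupled_pair_uses_pair_flips(self):
        m = model([5.0, 5.5], [True, True], [[0, 3.0], [3.0, 0]])
        ex = titrate_exact(m)
        mc = titrate_mc(m, seed=4, settings=MCSettings(burn_in=500, scans=20000))
        assert np.abs(mc.fractions - ex.fractions).max() <= 0.02


class TestPkaExtraction:
    def test_linear_midpoint(self):
        assert pka_from_curve([6.0, 6.2], [0.6, 0.4]) == pytest.approx(6.1)

    def test_exact_curve_on_coarse_grid_recovers_intrinsic(self):
        ph = np.arange(0.0, 14.01, 0.2)
        m = model([7.37], [True], ph=ph)
        r = titrate_exact(m)
        assert r.pka(0) == pytest.approx(7.37, abs=0.03)

    def test_no_crossing_is_an_error(self):
        ph = np.arange(5.0, 6.01, 0.2)
        with pytest.raises(TitrationError, match="widen"):
            pka_from_curve(ph, np.full(len(ph), 0.9))

    def test_multiple_crossings_pick_nearest_with_warning(self):
        ph = np.array([4.0, 5.0, 6.0, 7.0])
        f = np.array([0.6, 0.4, 0.6, 0.4])
        with pytest.warns(UserWarning, match="multiple"):
            assert pka_from_curve(ph, f, near=6.6) == pytest.approx(6.5)
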