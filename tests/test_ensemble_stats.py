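import numpy as np
import pytest

from pkagrid import synthetic_data as synth
from pkagrid.dielectric_model import DielectricScene, grid_from_structure
from pkagrid.ensemble_stats import (
    FrameLedger,
    averaged_pka,
    effective_sample_size,
    fluctuation_sd,
    per_frame_components,
)
from pkagrid.pka_engine import EnergyLedger
from pkagrid.structure_io import assign_parse, find_titratable_sites


def synthetic_ledger(totals, W=None, site_ids=None, model_pka=None, sites=None):
    """FrameLedger whose born shifts carry the requested per-frame totals."""
    totals = np.asarray(totals, dtype=float)
    n_frames, n_sites = totals.shape
    site_ids = site_ids or [f"s{i}" for i in range(n_sites)]
    frames = [
        EnergyLedger(
            site_ids=site_ids,
            model_pka=np.asarray(model_pka if model_pka is not None else [5.0] * n_sites),
            born_shift=totals[k].copy(),
            background_shift=np.zeros(n_sites),
            W=np.zeros((n_sites, n_sites)) if W is None else np.asarray(W, dtype=float),
            frame_id=k,
        )
        for k in range(n_frames)
    ]
    return FrameLedger(frames=frames, sites=sites)


class TestFluctuationSd:
    def test_sample_sd_of_simple_series(self):
        report = fluctuation_sd(synthetic_ledger([[1.0], [2.0], [3.0]]))
        assert report.sd_total_shift[0] == pytest.approx(1.0)
        assert report.mean_total_shift[0] == pytest.approx(2.0)

    def test_constant_series_has_zero_sd(self):
        report = fluctuation_sd(synthetic_ledger([[0.7, -1.1]] * 4))
        np.testing.assert_allclose(report.sd_total_shift, 0.0, atol=1e-15)

    def test_median_over_subset(self):
        totals = np.zeros((3, 3))
        totals[:, 0] = [0.0, 0.4, 0.8]   # sd 0.4
        totals[:, 1] = [0.0, 0.9, 1.8]   # sd 0.9
        totals[:, 2] = [0.0, 1.5, 3.0]   # sd 1.5
        report = fluctuation_sd(synthetic_ledger(totals))
        assert report.median_sd == pytest.approx(0.9)
        sub = fluctuation_sd(synthetic_ledger(totals), subset=["s0", "s1"])
        assert sub.median_sd == pytest.approx(0.65)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            fluctuation_sd(synthetic_ledger([[1.0]]))

    def test_sd_scales_linearly_with_noise_amplitude(self, rng):
        noise = rng.normal(size=(20, 2))
        r1 = fluctuation_sd(synthetic_ledger(1.0 * noise))
        r2 = fluctuation_sd(synthetic_ledger(2.0 * noise))
        np.testing.assert_allclose(r2.sd_total_shift, 2.0 * r1.sd_total_shift, rtol=1e-12)


class TestPairThreshold:
    def test_weak_pairs_excluded_from_totals(self):
        W_weak = [[0.0, 0.3], [0.3, 0.0]]
        W_strong = [[0.0, 0.7], [0.7, 0.0]]
        base = synthetic_ledger(np.ones((2, 2)), W=W_weak)
        strong = synthetic_ledger(np.ones((2, 2)), W=W_strong)
        # |W| = 0.3 < 0.5 contributes nothing; 0.7 does
        np.testing.assert_allclose(base.total_shift_matrix(), 1.0)
        assert not np.allclose(strong.total_shift_matrix(), 1.0)
        assert base.thresholded_pairs() == []
        assert len(strong.thresholded_pairs()) == 1

    def test_thresholding_only_removes_contributions(self):
        W = [[0.0, 0.3], [0.3, 0.0]]
        with_pairs = FrameLedger(
            frames=synthetic_ledger(np.ones((3, 2)), W=W).frames, pair_threshold=0.0
        )
        without = synthetic_ledger(np.ones((3, 2)), W=W)
        sd_with = fluctuation_sd(with_pairs).sd_total_shift
        sd_without = fluctuation_sd(without).sd_total_shift
        # excluded pairs are constant across frames here, so SDs agree
        np.testing.assert_allclose(sd_with, sd_without, atol=1e-12)


@pytest.fixture(scope="module")
def helix_frames():
    base = assign_parse(synth.make_helix_in_slab([("GLU", 4), ("LYS", 9)], n_residues=12))
    grid = grid_from_structure(base, spacing=1.0, margin=12.0)
    scene = DielectricScene(structure=base, ionic_strength=0.1)
    return base, grid, scene


class TestPerFrameComponents:
    def test_identical_frames_give_identical_components(self, helix_frames, engine_settings):
        base, grid, scene = helix_frames
        frames = synth.make_pseudo_trajectory(base, 0.0, 3, seed=0)
        ledger = per_frame_components(frames, grid, scene, settings=engine_settings)
        totals = ledger.total_shift_matrix()
        np.testing.assert_allclose(totals - totals[0], 0.0, atol=1e-12)

    def test_jitter_produces_fluctuations_increasing_with_sigma(self, helix_frames, engine_settings):
        base, grid, scene = helix_frames
        sds = []
        for sigma in (0.05, 0.25):
            frames = synth.make_pseudo_trajectory(base, sigma, 4, seed=3)
            ledger = per_frame_components(frames, grid, scene, settings=engine_settings)
            sds.append(fluctuation_sd(ledger).median_sd)
        assert 0 < sds[0] < sds[1]


class TestAveragedPka:
    def test_identical_frames_have_zero_uncertainty(self):
        sites = _two_fake_sites()
        ledger = synthetic_ledger(np.full((4, 2), 0.5), sites=sites)
        report = averaged_pka(ledger)
        np.testing.assert_allclose(report.pka_uncertainty, 0.0, atol=1e-12)
        np.testing.assert_allclose(report.averaged_pka, [5.5, 5.5], atol=0.02)

    def test_single_frame_flags_undefined_uncertainty(self):
        sites = _two_fake_sites()
        ledger = synthetic_ledger(np.zeros((1, 2)), sites=sites)
        report = averaged_pka(ledger)
        assert np.all(np.isnan(report.pka_uncertainty))
        np.testing.assert_allclose(report.averaged_pka, [5.0, 5.0], atol=0.02)

    def test_recovers_generating_pkas_on_noisy_ledgers(self, rng):
        sites = _two_fake_sites()
        true_shift = np.array([1.2, -0.8])
        totals = true_shift[None, :] + rng.normal(0, 0.3, size=(40, 2))
        ledger = synthetic_ledger(totals, sites=sites)
        report = averaged_pka(ledger)
        for i in range(2):
            err = abs(report.averaged_pka[i] - (5.0 + totals[:, i].mean()))
            assert err <= 0.05
            assert report.pka_uncertainty[i] < 0.2

    def test_averaging_orders_agree_for_uncoupled_sites(self, rng):
        sites = _two_fake_sites()
        totals = rng.normal(0, 0.2, size=(10, 2))
        ledger = synthetic_ledger(totals, sites=sites)
        r1 = averaged_pka(ledger, order="average-components")
        r2 = averaged_pka(ledger, order="average-pka")
        unc = np.nan_to_num(r1.pka_uncertainty, nan=0.0) + 0.05
        assert np.all(np.abs(r1.averaged_pka - r2.averaged_pka) <= 3 * unc)


class TestEffectiveSampleSize:
    def test_iid_series_keeps_nominal_n(self, rng):
        x = rng.normal(size=400)
        assert effective_sample_size(x) > 250

    def test_perfectly_correlated_series_collapses(self):
        x = np.repeat(np.arange(10.0), 20)
        assert effective_sample_size(x) < 30


def _two_fake_sites():
    from pkagrid.structure_io import TitratableSite

    return [
        TitratableSite(
            site_id=f"s{i}", residue_type="GLU", acid_or_base="acid", model_pka=5.0,
            protonated_charges={"CD": 1.0}, deprotonated_charges={"CD": 0.0},
            chain_id="A", residue_number=i + 1,
            atom_positions={"CD": np.array([3.0 * i, 0.0, 0.0])}, atom_indices={"CD": 0},
        )
        for i in range(2)
    ]
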