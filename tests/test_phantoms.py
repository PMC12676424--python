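"""Phantom geometry, texture statistics, and planted-signal construction."""

import numpy as np
import pytest

from layerlens import PhantomConfig, generate_cohort, generate_label_map, shear_speed_to_modulus
from layerlens.phantoms import generate_scan, load_cohort, write_cohort


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestShearConversion:
    @pytest.mark.parametrize("speed,modulus", [(0.0, 0.0), (1.0, 1000.0), (2.5, 6250.0)])
    def test_rho_c_squared(self, speed, modulus):
        assert shear_speed_to_modulus(speed) == pytest.approx(modulus)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            shear_speed_to_modulus(-0.1)


class TestLabelMapGeometry:
    def test_flat_equal_partition(self):
        config = PhantomConfig(grid_shape=(24, 8, 8), interface_wobble=0.0)
        lmap = generate_label_map(config, _rng())
        for code in range(1, 7):
            assert lmap.volume(code) == 4 * 8 * 8
        assert lmap.volume(0) == 0

    def test_wobble_bounded_voxel_counts(self):
        config = PhantomConfig(grid_shape=(30, 12, 12), interface_wobble=1.5)
        lmap = generate_label_map(config, _rng(3))
        slab = 5 * 12 * 12
        for code in range(1, 7):
            # each layer's two interfaces move at most `wobble` voxels
            assert abs(lmap.volume(code) - slab) <= 2 * 1.5 * 12 * 12

    def test_depth_stacked_order_and_presence(self):
        config = PhantomConfig(grid_shape=(32, 8, 8), interface_wobble=2.0)
        lmap = generate_label_map(config, _rng(1))
        assert lmap.present_codes() == [1, 2, 3, 4, 5, 6]
        # layer codes are non-decreasing with depth in every column
        nonzero = np.where(lmap.labels > 0, lmap.labels, 99)
        for h in range(8):
            for w in range(8):
                col = lmap.labels[:, h, w]
                inside = col[col > 0]
                assert np.all(np.diff(inside) >= 0)

    def test_deterministic_for_fixed_seed(self):
        config = PhantomConfig(grid_shape=(24, 8, 8))
        a = generate_label_map(config, _rng(9)).labels
        b = generate_label_map(config, _rng(9)).labels
        np.testing.assert_array_equal(a, b)

    def test_too_shallow_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_label_map(PhantomConfig(grid_shape=(8, 8, 8)), _rng())


class TestScanGeneration:
    CONFIG = PhantomConfig(grid_shape=(24, 16, 16), interface_wobble=0.0, seed=0)

    def test_control_layer_means_match_base(self):
        lmap = generate_label_map(self.CONFIG, _rng(0))
        rng = _rng(1)
        means = np.zeros(6)
        n_scans = 40
        for _ in range(n_scans):
            scan = generate_scan(self.CONFIG, lmap, is_positive=False, rng=rng)
            b = scan.channel("bmode").values
            for code in range(1, 7):
                means[code - 1] += b[lmap.labels == code].mean() / n_scans
        # layer mean = base * E[speckle] = base; SE ~ cv/sqrt(n_vox*n_scans)
        np.testing.assert_allclose(means, self.CONFIG.bmode_base, rtol=0.02)

    def test_additive_effect_recovered_in_signal_layer(self):
        config = PhantomConfig(grid_shape=(24, 16, 16), interface_wobble=0.0,
                               signal_layers=(5,), effect_bmode=0.5, seed=0)
        lmap = generate_label_map(config, _rng(0))
        rng = _rng(2)
        n = 100
        diff = np.zeros(6)
        for _ in range(n):
            pos = generate_scan(config, lmap, True, rng).channel("bmode").values
            neg = generate_scan(config, lmap, False, rng).channel("bmode").values
            for code in range(1, 7):
                m = lmap.labels == code
                diff[code - 1] += (pos[m].mean() - neg[m].mean()) / n
        assert diff[4] == pytest.approx(0.5, abs=0.05)
        np.testing.assert_allclose(np.delete(diff, 4), 0.0, atol=0.05)

    def test_swe_channel_non_negative_and_modulus_scaled(self):
        lmap = generate_label_map(self.CONFIG, _rng(0))
        scan = generate_scan(self.CONFIG, lmap, False, _rng(3))
        swe = scan.channel("swe").values
        assert np.all(swe >= 0)
        mus = [swe[lmap.labels == c].mean() for c in range(1, 7)]
        expected = 1000.0 * np.asarray(self.CONFIG.swe_base) ** 2
        np.testing.assert_allclose(mus, expected, rtol=0.1)

    def test_synergistic_marginals_null_but_pair_informative(self):
        """Each pair layer's mean carries no class signal, while the product
        of centered pair means separates the classes."""
        config = PhantomConfig(grid_shape=(24, 16, 16), interface_wobble=0.0,
                               signal_layers=(4, 5), effect_bmode=0.4,
                               interaction_mode="synergistic", seed=0)
        lmap = generate_label_map(config, _rng(0))
        rng = _rng(4)
        rows = []
        for y in (0, 1) * 100:
            scan = generate_scan(config, lmap, bool(y), rng)
            b = scan.channel("bmode").values
            rows.append((y, b[lmap.labels == 4].mean(), b[lmap.labels == 5].mean()))
        arr = np.asarray(rows)
        y, m4, m5 = arr[:, 0].astype(bool), arr[:, 1], arr[:, 2]
        for m in (m4, m5):
            se = np.sqrt(m[y].var() / y.sum() + m[~y].var() / (~y).sum())
            assert abs(m[y].mean() - m[~y].mean()) < 3 * se  # marginal null
        prod = (m4 - m4.mean()) * (m5 - m5.mean())
        # product is +e^2 for positives, -e^2 for controls
        assert prod[y].mean() > 0.1 > 0 > -0.1 > prod[~y].mean()

    def test_redundant_shift_duplicated(self):
        config = PhantomConfig(grid_shape=(24, 16, 16), interface_wobble=0.0,
                               signal_layers=(4, 5), effect_bmode=0.4,
                               interaction_mode="redundant", seed=0)
        lmap = generate_label_map(config, _rng(0))
        rng = _rng(5)
        m4, m5 = [], []
        for _ in range(50):
            b = generate_scan(config, lmap, True, rng).channel("bmode").values
            m4.append(b[lmap.labels == 4].mean() - config.bmode_base[3])
            m5.append(b[lmap.labels == 5].mean() - config.bmode_base[4])
        assert np.mean(m4) == pytest.approx(0.4, abs=0.05)
        assert np.mean(m5) == pytest.approx(0.4, abs=0.05)

    def test_unknown_signal_layer_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(signal_layers=(0,))


class TestCohorts:
    def test_scan_counting(self):
        config = PhantomConfig(grid_shape=(16, 8, 8), n_patients=4,
                               visits_per_patient=1, sites_per_side=2,
                               bmode_reps=3, swe_reps=2, seed=0)
        cohort = generate_cohort(config)
        assert len(cohort.scans) == 4 * 1 * 2 * 2 * 3 == 48
        with_swe = [s for s in cohort.scans if "swe" in s.modalities]
        assert len(with_swe) == 4 * 1 * 2 * 2 * 2

    def test_extreme_prevalence_boundary(self):
        config = PhantomConfig(grid_shape=(16, 8, 8), n_patients=3,
                               visits_per_patient=1, sites_per_side=1,
                               bmode_reps=1, swe_reps=1, prevalence=0.999999,
                               seed=1)
        cohort = generate_cohort(config)
        assert cohort.truth["side_positive"].all()
        assert (cohort.index.manifest["scan_label"] != "control").all()

    def test_truth_consistent_with_manifest_labels(self, tiny_cohort):
        merged = tiny_cohort.truth.merge(tiny_cohort.index.manifest, on="scan_id")
        assert ((merged["scan_label"] != "control")
                == merged["side_positive"]).all()

    def test_seed_reproducibility(self):
        config = PhantomConfig(grid_shape=(16, 8, 8), n_patients=2,
                               visits_per_patient=1, sites_per_side=1, seed=42)
        a, b = generate_cohort(config), generate_cohort(config)
        assert a.index.manifest.equals(b.index.manifest)
        np.testing.assert_array_equal(a.scans[0].channels[0].values,
                                      b.scans[0].channels[0].values)

    def test_cohort_directory_roundtrip(self, tiny_cohort, tmp_path):
        write_cohort(tiny_cohort, tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort")
        assert len(back.scans) == len(tiny_cohort.scans)
        orig = {s.scan_id: s for s in tiny_cohort.scans}
        for scan in back.scans:
            np.testing.assert_allclose(
                scan.channels[0].values, orig[scan.scan_id].channels[0].values,
                rtol=1e-5)
            np.testing.assert_array_equal(
                back.label_maps[scan.scan_id].labels,
                tiny_cohort.label_maps[scan.scan_id].labels)
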