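import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from libscal import simulate as sim
from libscal.dataset import SpectralDataset


class TestBuildAxis:
    def test_full_resolution_axis(self):
        axis = sim.build_axis(229.99, 880.01, 22015)
        assert axis.size == 22015
        assert axis[0] == 229.99 and axis[-1] == 880.01
        spacing = np.diff(axis)
        assert np.allclose(spacing, (880.01 - 229.99) / 22014)
        assert spacing[0] == pytest.approx(650.02 / 22014, rel=1e-12)

    @pytest.mark.parametrize(
        "lo,hi,n,expected",
        [(0, 1, 2, [0, 1]), (0, 10, 11, list(range(11)))],
    )
    def test_small_grids(self, lo, hi, n, expected):
        assert np.allclose(sim.build_axis(lo, hi, n), expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sim.build_axis(0, 1, 1)
        with pytest.raises(ValueError):
            sim.build_axis(5, 1, 10)


class TestLineProfile:
    def test_zero_height_is_all_zero(self):
        axis = sim.build_axis(400, 410, 101)
        assert not sim.line_profile(405, 0.1, 0.0, axis).any()

    def test_peak_channel_equals_height(self):
        axis = sim.build_axis(400, 410, 101)
        prof = sim.line_profile(405.03, 0.1, 7.5, axis, lorentz_fraction=0.4)
        assert prof.max() == pytest.approx(7.5)
        assert axis[np.argmax(prof)] == pytest.approx(405.0)

    def test_gaussian_half_maximum_at_half_width(self):
        # grid points exactly at center and center +/- FWHM/2
        axis = sim.build_axis(404.0, 406.0, 81)  # 0.025 nm spacing
        prof = sim.line_profile(405.0, 0.1, 2.0, axis, lorentz_fraction=0.0)
        i = np.argmin(np.abs(axis - 405.0))
        half = np.argmin(np.abs(axis - 405.05))
        assert prof[i] == pytest.approx(2.0, abs=1e-12)
        assert prof[half] == pytest.approx(1.0, abs=1e-9)

    def test_invalid_width(self):
        axis = sim.build_axis(400, 410, 11)
        with pytest.raises(ValueError):
            sim.line_profile(405, 0.0, 1.0, axis)


def _noiseless(**kw):
    base = dict(
        group_sizes=(2, 2, 2, 2, 2),
        n_channels=1200,
        replicates=1,
        shot_sigma=0.0,
        noise_sigma=0.0,
        matrix_trend=0.0,
        seed=5,
    )
    base.update(kw)
    return sim.small_config(**base)


class TestSimulateSample:
    # analyte-only catalog isolates the Cd signal from the constant
    # matrix/background contributions at neighbouring channels
    def _analyte_only(self):
        lines = tuple(l for l in sim.default_line_catalog() if l.kind == "analyte")
        return _noiseless(lines=lines)

    def test_zero_concentration_gives_no_cd_peak(self):
        cfg = self._analyte_only()
        rng = np.random.default_rng(0)
        spec = sim.simulate_sample(cfg, 0.0, rng)
        i = np.argmin(np.abs(spec.wavelengths - 508.58))
        assert spec.intensities[i] == pytest.approx(0.0, abs=1e-12)

    def test_peak_height_linear_in_concentration(self):
        cfg = self._analyte_only()
        i508 = np.argmin(np.abs(cfg.axis() - 508.58))
        rng = np.random.default_rng(0)
        one = sim.simulate_sample(cfg, 2.0, rng).intensities[i508]
        two = sim.simulate_sample(cfg, 4.0, rng).intensities[i508]
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_same_seed_bit_identical(self):
        cfg = sim.small_config(n_channels=1200, seed=9)
        a = sim.simulate_sample(cfg, 3.0, np.random.default_rng(42))
        b = sim.simulate_sample(cfg, 3.0, np.random.default_rng(42))
        assert np.array_equal(a.intensities, b.intensities)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_sample(_noiseless(), -1.0, np.random.default_rng(0))


class TestSimulateDataset:
    def test_row_and_reference_counts(self):
        data = sim.simulate_dataset(_noiseless())
        assert data.n == 10 and data.reference.size == 10 and len(data.ids) == 10

    def test_fixed_seed_reproducible(self):
        cfg = sim.small_config(n_channels=1200, group_sizes=(2, 2, 2, 2, 2), seed=3)
        a = sim.simulate_dataset(cfg)
        b = sim.simulate_dataset(cfg)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.reference, b.reference)

    def test_replicate_averaging_shrinks_channel_variance(self):
        # Monte-Carlo: the same channel across many seeds fluctuates less
        # when each pellet averages more shots.
        def channel_sd(replicates):
            vals = []
            for seed in range(120):
                cfg = sim.small_config(
                    group_sizes=(1,),
                    group_means=(5.0,),
                    group_sds=(0.0,),
                    n_channels=300,
                    replicates=replicates,
                    seed=seed,
                )
                d = sim.simulate_dataset(cfg)
                vals.append(d.intensities[0, 150])
            return np.std(vals)

        assert channel_sd(8) < channel_sd(1)

    def test_group_means_recovered(self):
        # Groups whose mean is far from zero are essentially untruncated.
        sizes = (60, 60)
        cfg = sim.small_config(
            group_sizes=sizes,
            group_means=(6.663, 11.577),
            group_sds=(1.735, 2.617),
            n_channels=300,
            replicates=1,
            seed=11,
        )
        d = sim.simulate_dataset(cfg)
        ref = d.reference
        for gi, (m, sd, ns) in enumerate(zip(cfg.group_means, cfg.group_sds, sizes)):
            got = ref[gi * ns : (gi + 1) * ns].mean()
            assert abs(got - m) < 3 * sd / np.sqrt(ns)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_dataset(
                sim.small_config(group_sizes=(0, 2, 2, 2, 2), n_channels=300)
            )


class TestInvariants:
    def test_noiseless_peak_exactly_affine_in_concentration(self):
        cfg = _noiseless(group_sizes=(3, 3, 3, 3, 3))
        d = sim.simulate_dataset(cfg)
        i508 = d.nearest_channel(508.58)
        x = d.intensities[:, i508]
        coef = np.polyfit(d.reference, x, 1)
        fit = np.polyval(coef, d.reference)
        ss_res = np.sum((x - fit) ** 2)
        ss_tot = np.sum((x - x.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 1 - 1e-10

    def test_ratio_cancels_shared_shot_factor(self):
        # With additive noise off, the 508.58/466.23 peak ratio does not
        # depend on the per-shot multiplicative factor.
        cfg = _noiseless(shot_sigma=0.5, replicates=1)
        rng = np.random.default_rng(8)
        axis = cfg.axis()
        i508 = np.argmin(np.abs(axis - 508.58))
        i466 = np.argmin(np.abs(axis - 466.23))
        ratios = [
            sim.simulate_sample(cfg, 4.0, rng).intensities[[i508, i466]]
            for _ in range(6)
        ]
        vals = [a / b for a, b in ratios]
        assert np.ptp(vals) < 1e-12


class TestFileFormats:
    def test_dataset_roundtrip(self, tmp_path):
        d = sim.simulate_dataset(_noiseless())
        path = tmp_path / "data.csv"
        d.to_csv(path)
        back = SpectralDataset.from_csv(path)
        assert np.array_equal(back.wavelengths, d.wavelengths)
        assert np.array_equal(back.intensities, d.intensities)
        assert np.array_equal(back.reference, d.reference)
        assert back.ids == d.ids

    def test_catalog_and_config_roundtrip(self, tmp_path):
        cfg = sim.small_config(seed=4)
        cat = tmp_path / "catalog.csv"
        conf = tmp_path / "sim.yaml"
        sim.write_config(cfg, conf, catalog_path=cat)
        back = sim.read_config(conf)
        assert back == cfg


@given(st.floats(0.2, 5.0), st.floats(0.5, 100.0))
def test_profile_scaling_homogeneous(width, height):
    axis = sim.build_axis(400, 410, 201)
    one = sim.line_profile(405.0, width, 1.0, axis, 0.3)
    scaled = sim.line_profile(405.0, width, height, axis, 0.3)
    assert np.allclose(scaled, height * one, rtol=1e-12, atol=1e-12)
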