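"""Raman preprocessing and unmixing: contracts and recovery properties."""

import numpy as np
import pytest

import nanouptake as nu
from nanouptake.bands import default_axis, default_library
from nanouptake.raman import (
    NFINDR,
    DegeneratePixelError,
    EndmemberSet,
    RamanCube,
    band_intensity_image,
    classify_endmembers,
    cosine_similarity,
    cut_silent_region,
    despike,
    nnls_abundances,
    nnls_matrix,
    normalize_mean,
    peak_positions,
    preprocess,
    snip_baseline,
)

AXIS = default_axis()
LIB = default_library()


def _match(recovered, truth):
    """Greedy permutation match by cosine similarity; returns the sims."""
    sims = np.array(
        [[cosine_similarity(r, t) for t in truth] for r in recovered]
    )
    out = []
    used = set()
    for i in range(sims.shape[0]):
        j = int(np.argmax([s if k not in used else -2
                           for k, s in enumerate(sims[i])]))
        used.add(j)
        out.append((j, sims[i, j]))
    return out


class TestDespike:
    def test_smooth_spectrum_unchanged(self):
        x = np.linspace(0, 6 * np.pi, 400)
        s = 2.0 + np.sin(x)
        np.testing.assert_array_equal(despike(s), s)

    def test_spike_flattened_toward_neighbors(self):
        rng = np.random.default_rng(0)
        s = 10.0 + rng.normal(0, 0.3, 500)
        s[250] += 50 * np.median(s)
        out = despike(s)
        local = np.r_[s[240:250], s[251:261]]
        mad = np.median(np.abs(local - np.median(local)))
        assert abs(out[250] - np.median(local)) < 3 * max(mad, 0.3)
        # unspiked channels untouched
        keep = np.ones(500, bool)
        keep[248:253] = False
        np.testing.assert_array_equal(out[keep], s[keep])

    def test_band_maxima_survive_despiking(self, noisy_raman):
        clean_ref = LIB.reference_spectrum("polystyrene", AXIS)
        rng = np.random.default_rng(5)
        s = 1.6 * clean_ref + rng.normal(0, 0.05, AXIS.size)
        spiked = s.copy()
        spiked[700] += 30 * s.max()
        out = despike(spiked)
        sel = AXIS < 1800
        assert AXIS[sel][np.argmax(out[sel])] == AXIS[sel][np.argmax(s[sel])]

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            despike(np.ones(6), window=5)


class TestSnipBaseline:
    def test_constant_spectrum_fully_absorbed(self):
        s = np.full(300, 7.5)
        baseline, corrected = snip_baseline(s, 60)
        np.testing.assert_allclose(baseline, s, atol=1e-9)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)

    def test_narrow_peak_on_ramp_preserved(self):
        # normalized-intensity scale: the compressive LLS transform is
        # nearly linear there, so the planted amplitude survives clipping
        n = 500
        x = np.arange(n)
        ramp = 0.5 + 0.002 * x
        peak = 1.0 * np.exp(-4 * np.log(2) * ((x - 250) / 10.0) ** 2)
        baseline, corrected = snip_baseline(ramp + peak, 60)
        assert corrected[250] == pytest.approx(1.0, rel=0.05)

    def test_baseline_never_exceeds_spectrum(self, noisy_raman):
        mat = noisy_raman.cube.as_matrix()[::400]
        for s in mat:
            _, corrected = snip_baseline(s, 60)
            assert corrected.min() >= -0.01 * s.max()

    def test_iteration_bounds(self):
        with pytest.raises(ValueError):
            snip_baseline(np.ones(10), 0)
        with pytest.raises(ValueError):
            snip_baseline(np.ones(10), 10)


class TestNormalizeAndCut:
    def test_constant_normalizes_to_one(self):
        np.testing.assert_allclose(normalize_mean(np.full(50, 5.0)), 1.0)

    def test_mean_exactly_one(self, noisy_raman):
        s = noisy_raman.cube.as_matrix()[123]
        assert normalize_mean(s).mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum_degenerate(self):
        with pytest.raises(DegeneratePixelError):
            normalize_mean(np.zeros(100))

    def test_silent_region_channel_arithmetic(self):
        cube = RamanCube(
            axis=AXIS, intensities=np.ones((1, 2, 2, AXIS.size))
        )
        out = cut_silent_region(cube)
        assert not ((out.axis > 1800) & (out.axis < 2700)).any()
        # endpoints on the grid are retained
        assert 1800.0 in out.axis and 2700.0 in out.axis
        assert out.axis.size == AXIS.size - 449
        assert 1000.0 in out.axis

    def test_axis_without_silent_region_unchanged(self):
        ax = np.arange(600.0, 1700.0, 2.0)
        cube = RamanCube(axis=ax, intensities=np.ones((1, 1, 1, ax.size)))
        out = cut_silent_region(cube, (1800.0, 2700.0))
        assert out.axis.size == ax.size

    def test_region_swallowing_whole_axis_rejected(self):
        ax = np.arange(600.0, 1700.0, 2.0)
        cube = RamanCube(axis=ax, intensities=np.ones((1, 1, 1, ax.size)))
        with pytest.raises(ValueError):
            cut_silent_region(cube, (500.0, 3400.0))


class TestPreprocess:
    def test_flat_cube_all_degenerate(self):
        cube = RamanCube(
            axis=AXIS, intensities=np.full((1, 3, 3, AXIS.size), 4.0)
        )
        out, flags = preprocess(cube)
        assert flags.all()
        assert (out.as_matrix() == 0).all()

    def test_retained_pixels_have_unit_mean(self, noisy_raman):
        out, flags = preprocess(noisy_raman.cube)
        mat = out.as_matrix()[~flags.reshape(-1)]
        np.testing.assert_allclose(mat.mean(axis=1), 1.0, atol=1e-9)

    def test_second_pass_is_nearly_stable(self, noisy_raman):
        once, flags = preprocess(noisy_raman.cube)
        twice, _ = preprocess(once)
        a, b = once.as_matrix(), twice.as_matrix()
        rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(a**2))
        assert rms < 0.05

    def test_scale_equivariance_up_to_snip_nonlinearity(self, noisy_raman):
        s = noisy_raman.cube.as_matrix()[777]
        cube1 = RamanCube(axis=AXIS, intensities=s.reshape(1, 1, 1, -1))
        cube3 = RamanCube(
            axis=AXIS, intensities=(3.0 * s).reshape(1, 1, 1, -1)
        )
        a = preprocess(cube1)[0].as_matrix()[0]
        b = preprocess(cube3)[0].as_matrix()[0]
        rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(a**2))
        assert rms < 0.05

    def test_peak_positions_preserved_through_pipeline(self):
        fx = nu.make_raman_fixture(
            grid=(24, 24), n_z=1, snr=10.0, spike_fraction=0.01, seed=8
        )
        out, flags = preprocess(fx.cube)
        # the purest polystyrene pixel keeps its fingerprint maximum put
        ps = fx.truth_abundance.maps[2][0]
        assert ps.max() > 0.9
        iy, ix = np.unravel_index(np.argmax(ps), ps.shape)
        assert not flags[0, iy, ix]
        s = out.intensities[0, iy, ix]
        sel = out.axis < 1800
        assert abs(out.axis[sel][np.argmax(s[sel])] - 1001.0) <= 2.0


class TestNFINDR:
    def test_identical_spectra_k1(self):
        s = LIB.reference_spectrum("lipid", AXIS)
        X = np.tile(s, (20, 1))
        est = NFINDR(n_endmembers=1, random_state=0).fit(X)
        np.testing.assert_allclose(est.endmembers_[0], s)

    def test_noiseless_recovery_with_pure_pixels(self, noiseless_raman):
        fx = noiseless_raman
        est = NFINDR(n_endmembers=3, n_restarts=5, random_state=0)
        est.fit(fx.cube.as_matrix())
        for _, sim in _match(est.endmembers_, fx.truth_endmembers.spectra):
            assert sim >= 0.999

    def test_volume_path_strictly_increasing(self, noiseless_raman):
        est = NFINDR(n_endmembers=3, n_restarts=1, random_state=1)
        est.fit(noiseless_raman.cube.as_matrix())
        path = est.volume_path_
        assert all(b > a for a, b in zip(path, path[1:]))

    def test_k_exceeding_pixels_rejected(self):
        X = np.random.default_rng(0).random((5, 40))
        with pytest.raises(ValueError):
            NFINDR(n_endmembers=6).fit(X)

    def test_rank_deficient_cube_rejected(self):
        s = LIB.reference_spectrum("water", AXIS)
        X = np.outer(np.linspace(1, 2, 50), s)  # one distinct component
        with pytest.raises(ValueError, match="fewer distinct components"):
            NFINDR(n_endmembers=3, random_state=0).fit(X)


class TestNNLS:
    def test_pure_pixel_gets_unit_abundance(self):
        E = np.stack(
            [LIB.reference_spectrum(c, AXIS) for c in ("water", "lipid")]
        )
        A, r = nnls_matrix(E[1][None], E)
        np.testing.assert_allclose(A[0], [0.0, 1.0], atol=1e-8)
        assert r[0] < 1e-8

    def test_known_mixture_recovered(self):
        E = np.stack(
            [
                LIB.reference_spectrum(c, AXIS)
                for c in ("water", "lipid", "polystyrene")
            ]
        )
        mix = 0.3 * E[0] + 0.7 * E[1]
        A, _ = nnls_matrix(mix[None], E)
        np.testing.assert_allclose(A[0], [0.3, 0.7, 0.0], atol=1e-6)

    def test_zero_spectrum_zero_abundance(self):
        E = np.stack(
            [LIB.reference_spectrum(c, AXIS) for c in ("water", "lipid")]
        )
        A, _ = nnls_matrix(np.zeros((1, AXIS.size)), E)
        np.testing.assert_array_equal(A[0], 0.0)

    def test_abundances_nonnegative_on_noisy_cube(self, noisy_raman):
        sub = RamanCube(
            axis=noisy_raman.cube.axis,
            intensities=noisy_raman.cube.intensities[:1, :10, :10],
        )
        ems = EndmemberSet(
            axis=AXIS, spectra=noisy_raman.truth_endmembers.spectra
        )
        ab = nnls_abundances(sub, ems)
        assert (ab.maps >= 0).all()

    def test_truth_endmembers_reconstruct_noiseless_cube(
        self, noiseless_raman
    ):
        fx = noiseless_raman
        ab = nnls_abundances(fx.cube, fx.truth_endmembers)
        E = fx.truth_endmembers.spectra
        rec = np.tensordot(ab.maps, E, axes=([0], [0]))
        err = np.abs(rec - fx.cube.intensities).max()
        assert err < 1e-6 * fx.cube.intensities.max()

    def test_dependent_endmembers_rejected(self):
        s = LIB.reference_spectrum("water", AXIS)
        ems = EndmemberSet(axis=AXIS, spectra=np.stack([s, 2 * s]))
        cube = RamanCube(axis=AXIS, intensities=s.reshape(1, 1, 1, -1))
        with pytest.raises(ValueError):
            nnls_abundances(cube, ems)


class TestBandImageAndClassification:
    def test_uniform_cube_uniform_image(self):
        cube = RamanCube(
            axis=AXIS, intensities=np.full((2, 3, 3, AXIS.size), 2.0)
        )
        img = band_intensity_image(cube)
        assert np.ptp(img.images) == 0
        assert img.window == (987.5, 1012.5)

    def test_polystyrene_regions_light_up(self, noiseless_raman):
        fx = noiseless_raman
        img = band_intensity_image(fx.cube, 1000.0, 25.0)
        ps = fx.layout_mask("polystyrene")
        water = fx.layout == 0
        assert img.images[ps].mean() > 3 * img.images[water].mean()

    def test_window_inside_cut_region_rejected(self, noisy_raman):
        pre, _ = preprocess(noisy_raman.cube)
        with pytest.raises(ValueError):
            band_intensity_image(pre, 2200.0, 25.0)

    def test_reference_spectra_classified_correctly(self):
        E = np.stack(
            [
                LIB.reference_spectrum(c, AXIS)
                for c in ("polystyrene", "lipid", "water")
            ]
        )
        ems = classify_endmembers(EndmemberSet(axis=AXIS, spectra=E))
        assert ems.labels == ["polystyrene", "lipid", "water"]

    def test_noise_is_unassigned(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1, AXIS.size)
        ems = classify_endmembers(
            EndmemberSet(axis=AXIS, spectra=noise[None])
        )
        assert ems.labels == ["unassigned"]

    def test_scaled_copies_share_a_label(self):
        s = LIB.reference_spectrum("polystyrene", AXIS)
        ems = classify_endmembers(
            EndmemberSet(axis=AXIS, spectra=np.stack([s, 2 * s]))
        )
        assert ems.labels == ["polystyrene", "polystyrene"]


class TestPeakPositions:
    def test_single_gaussian(self):
        s = np.exp(-0.5 * ((AXIS - 1001) / 5.0) ** 2)
        peaks = peak_positions(AXIS, s)
        assert len(peaks) == 1 and abs(peaks[0] - 1001) <= 2.0

    def test_polystyrene_reference_peaks(self):
        s = LIB.reference_spectrum("polystyrene", AXIS)
        peaks = peak_positions(AXIS, s)
        for c in (621, 1001, 1604):
            assert np.min(np.abs(peaks - c)) <= 2.0

    def test_flat_spectrum_no_peaks(self):
        assert peak_positions(AXIS, np.zeros(AXIS.size)).size == 0
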