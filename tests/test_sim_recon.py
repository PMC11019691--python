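"""Band separation, pattern estimation, Wiener combination, reconstruction."""

import numpy as np
import pytest

from mfsim import (
    IlluminationPattern,
    ReconOptions,
    estimate_pattern,
    reconstruct_volume,
    rl_deconvolve,
    separate_bands,
    widefield_average,
    wiener_combine,
)
from mfsim.errors import DimensionError, ReconstructionError
from mfsim.optics_core import generate_psf, pattern_wavevector
from mfsim.sim_recon import PatternEstimate, _group_planes, radial_otf


def _synthetic_frames(n_phases, n_orders, shape=(32, 32), seed=0):
    """Frames built from known complex bands; returns (frames, bands)."""
    rng = np.random.default_rng(seed)
    ms = np.arange(n_orders) - n_orders // 2
    bands = {}
    for m in ms:
        if m == 0:
            b = rng.normal(size=shape)
            bands[0] = np.fft.fft2(b)
        elif m > 0:
            b = rng.normal(size=shape) + 1j * rng.normal(size=shape)
            bands[m] = np.fft.fft2(b)
            bands[-m] = np.conj(bands[m][(-np.arange(shape[0])) % shape[0]][:, (-np.arange(shape[1])) % shape[1]])
    frames = []
    for j in range(n_phases):
        phi = 2 * np.pi * j / n_phases
        spec = sum(bands[m] * np.exp(1j * m * phi) for m in ms)
        frames.append(np.fft.ifft2(spec).real)
    return np.stack(frames), bands


class TestSeparateBands:
    def test_identical_frames_have_zero_modulated_orders(self):
        frames = np.stack([np.outer(np.hanning(16), np.hanning(16))] * 5)
        bands = separate_bands(frames, 5)
        common = np.fft.fft2(frames[0])
        assert np.allclose(bands[0], common, atol=1e-10)
        for m in (-2, -1, 1, 2):
            assert np.max(np.abs(bands[m])) < 1e-10 * np.max(np.abs(common))

    @pytest.mark.parametrize("n_phases,n_orders", [(5, 5), (3, 3), (7, 5)])
    def test_known_bands_recovered_to_machine_precision(self, n_phases, n_orders):
        """Exact inversion (square) and least squares (overdetermined),
        cross-checked against an independent per-pixel lstsq solve."""
        frames, truth = _synthetic_frames(n_phases, n_orders)
        got = separate_bands(frames, n_orders)
        for m, spec in truth.items():
            assert np.allclose(got[m], spec, atol=1e-8)
        # independent oracle: pixelwise lstsq of the mixing system
        ms = np.arange(n_orders) - n_orders // 2
        phases = 2 * np.pi * np.arange(n_phases) / n_phases
        mix = np.exp(1j * np.outer(phases, ms))
        spectra = np.fft.fft2(frames, axes=(-2, -1)).reshape(n_phases, -1)
        oracle, *_ = np.linalg.lstsq(mix, spectra, rcond=None)
        for i, m in enumerate(ms):
            assert np.allclose(got[m].ravel(), oracle[i], atol=1e-8)

    def test_phase_shift_theorem_on_recovered_orders(self):
        """Shifting all five phases by delta multiplies order m by
        exp(i m delta) (checked analytically for m = 2, delta = pi/5)."""
        frames, _ = _synthetic_frames(5, 5, seed=4)
        delta = np.pi / 5
        base = separate_bands(frames, 5)
        shifted_phases = 2 * np.pi * np.arange(5) / 5 + delta
        # rebuild frames with shifted phases from the recovered bands
        ms = np.arange(5) - 2
        frames2 = np.stack([
            np.fft.ifft2(sum(base[m] * np.exp(1j * m * p) for m in ms)).real
            for p in shifted_phases
        ])
        got = separate_bands(frames2, 5)
        ratio = got[2][np.abs(base[2]) > 1] / base[2][np.abs(base[2]) > 1]
        assert np.allclose(ratio, np.exp(2j * delta), atol=1e-6)

    def test_duplicate_phases_rejected(self):
        frames, _ = _synthetic_frames(5, 5)
        with pytest.raises(ReconstructionError):
            separate_bands(frames, 5, phases=np.zeros(5))
        with pytest.raises(DimensionError):
            separate_bands(frames[:3], 5)


@pytest.fixture(scope="module")
def grouped(noiseless_bead_acquisition, bead_tile_map):
    return _group_planes(noiseless_bead_acquisition, bead_tile_map, 0, 0)


@pytest.fixture(scope="module")
def otf(optics):
    psf = generate_psf(optics, (9, 97, 97), (132.0, optics.px_sample, optics.px_sample))
    return radial_otf(psf)


class TestEstimatePattern:
    def test_wave_vector_phase_and_orientation(self, grouped, otf, optics):
        """Noiseless simulation at the nominal pattern: wave vector within
        0.2 %, starting phase within 0.02 rad, orientations 60 +/- 0.2 deg
        apart (simulator ground truth as oracle)."""
        pat = IlluminationPattern()
        angles = []
        for o in range(3):
            pooled = [separate_bands(grouped[p, o], 5) for p in (3, 0, 1, 2, 4, 5, 6)]
            est = estimate_pattern(pooled, otf=otf, spacing=optics.px_sample,
                                   k_prior=pattern_wavevector(pat, o),
                                   beam_mode="three_beam")
            kmag = np.linalg.norm(est.k_fine)
            assert kmag == pytest.approx(1.0 / 237.0, rel=0.002)
            phase = (est.phase + np.pi) % (2 * np.pi) - np.pi
            assert abs(phase) < 0.02
            angles.append(est.angle_deg)
            assert est.angle_deg == pytest.approx(pat.orientations[o], abs=0.1)
        diffs = np.diff(sorted(angles))
        assert np.allclose(diffs, 60.0, atol=0.2)

    def test_modulation_depths_match_equal_beam_theory(self, grouped, otf, optics):
        """Equal three-beam amplitudes: intensity harmonics 3 : 2 : 1, so
        m1 = 4/3 and m2 = 2/3 relative to order 0."""
        pat = IlluminationPattern()
        bands = separate_bands(grouped[3, 0], 5)
        est = estimate_pattern(bands, otf=otf, spacing=optics.px_sample,
                               k_prior=pattern_wavevector(pat, 0),
                               beam_mode="three_beam")
        assert est.m1 == pytest.approx(4 / 3, rel=0.05)
        assert est.m2 == pytest.approx(2 / 3, rel=0.05)


class TestWienerCombine:
    def test_identity_limit_single_order_flat_otf(self, optics):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.poisson(100, (64, 64)).astype(float), 2)
        # band-limit the input to the extended cutoff the combiner passes
        spec = np.fft.fft2(img)
        k = np.fft.fftfreq(64, 64.5)
        kmag = np.hypot(k[:, None], k[None, :])
        pat = IlluminationPattern()
        k_ext = 2 * 1.4 / 525.0 + 1.0 / pat.period
        img = np.fft.ifft2(spec * (kmag <= k_ext)).real
        est = PatternEstimate(k_fine=pattern_wavevector(pat, 0), phase=0.0,
                              m1=0.0, amps={0: 1.0 + 0j})
        opts = ReconOptions(wiener_w=1e-4, notch_depth=0.0, upsample=1,
                            apodization="none")
        out = wiener_combine({0: {0: np.fft.fft2(img)}}, {0: est},
                             lambda k: np.ones_like(np.asarray(k, dtype=float)),
                             optics, pat, opts=opts)
        assert np.allclose(out, img, rtol=1e-4, atol=1e-4 * img.max())

    def test_spectral_support_extends_by_1p74(
        self, noiseless_bead_acquisition, bead_tile_map, optics
    ):
        """Radial spectral support of the reconstructed plane vs the
        widefield plane, at the 1e-3 radial-energy threshold: factor
        1.74 +/- 0.1.  Noiseless data and the linear (pre-clamp) combiner
        output, so the support is not masked by noise floors."""
        raw = noiseless_bead_acquisition
        pat = raw.pattern
        grouped = _group_planes(raw, bead_tile_map, 0, 0)
        psf = generate_psf(optics, (9, 97, 97),
                           (132.0, optics.px_sample, optics.px_sample))
        otf = radial_otf(psf)
        bands_o, ests = {}, {}
        for o in range(3):
            pooled = [separate_bands(grouped[p, o], 5) for p in (3, 0, 1, 2, 4, 5, 6)]
            bands_o[o] = pooled[0]
            ests[o] = estimate_pattern(pooled, otf=otf, spacing=optics.px_sample,
                                       k_prior=pattern_wavevector(pat, o),
                                       beam_mode="three_beam")
        plane = wiener_combine(bands_o, ests, otf, optics, pat)
        wf = widefield_average(raw, bead_tile_map)

        class recon:  # minimal container for the shared assertions below
            data = {3: plane}
            voxel = (264.0, optics.px_sample / 2, optics.px_sample / 2)

        def support(img, spacing):
            spec = np.abs(np.fft.fft2(img - img.mean()))
            k = np.fft.fftfreq(img.shape[0], spacing)
            kmag = np.hypot(k[:, None], k[None, :])
            prof_k = np.linspace(0, kmag.max(), 200)
            # last radius with azimuthal mean energy above threshold
            dc = spec.max()
            keep = prof_k[
                [spec[(kmag >= a) & (kmag < b)].mean() > 1e-3 * dc
                 for a, b in zip(prof_k[:-1], prof_k[1:])] + [False]
            ]
            return keep.max()

        s_recon = support(recon.data[3], recon.voxel[1])
        s_wf = support(wf.data[3], wf.voxel[1])
        assert s_recon / s_wf == pytest.approx(1.74, abs=0.1)

    def test_rejects_nonpositive_wiener_parameter(self):
        with pytest.raises(ReconstructionError):
            ReconOptions(wiener_w=0.0)


class TestReconstructVolume:
    def test_seven_planes_at_264nm_without_stepping(
        self, bead_acquisition, bead_tile_map
    ):
        recon = reconstruct_volume(bead_acquisition, bead_tile_map)
        assert recon.data.shape[0] == 7
        assert np.allclose(np.diff(recon.z_offsets), 264.0)
        assert recon.voxel[1] == pytest.approx(bead_acquisition.optics.px_sample / 2)
        assert recon.data.min() >= 0.0

    def test_interleaved_zsteps_merge_to_132nm_stack(self, optics):
        from mfsim import (
            AcquisitionTiming,
            CameraConfig,
            MultifocusConfig,
            make_sheet_phantom,
            simulate_acquisition,
            simulate_widefield_zscan,
        )
        from mfsim.registration import calibrate_tile_map

        px = optics.px_sample
        ph = make_sheet_phantom((11, 64, 64), (132.0, px, px),
                                z_planes_nm=(5 * 132.0,), seed=1)
        ph.volume *= 200.0
        mf = MultifocusConfig(tile_px=64)
        cam = CameraConfig(frame_px=(232, 232))
        timing = AcquisitionTiming(n_zsteps=2, zstep_nm=132.0)
        raw = simulate_acquisition(ph, IlluminationPattern(), optics, mf, cam,
                                   timing=timing, seed=0)
        scan = simulate_widefield_zscan(ph, optics, mf, cam, n_steps=7,
                                        zstep_nm=264.0, seed=1)
        tm = calibrate_tile_map(scan)
        recon = reconstruct_volume(raw, tm)
        assert recon.data.shape[0] == 14
        assert np.all(np.diff(recon.z_offsets) > 0)
        assert np.allclose(np.diff(recon.z_offsets), 132.0)

    def test_flat_field_reconstructs_flat(self, optics):
        from mfsim import CameraConfig, MultifocusConfig, simulate_acquisition, simulate_widefield_zscan
        from mfsim.phantoms import uniform_phantom
        from mfsim.registration import calibrate_tile_map

        px = optics.px_sample
        ph = uniform_phantom((1, 96, 96), (132.0, px, px), value=100.0)
        mf = MultifocusConfig(tile_px=96)
        cam = CameraConfig(frame_px=(328, 328))
        raw = simulate_acquisition(ph, IlluminationPattern(), optics, mf, cam,
                                   seed=1, noise=False)
        tm = calibrate_tile_map(simulate_widefield_zscan(ph, optics, mf, cam,
                                                         n_steps=7, zstep_nm=264.0,
                                                         noise=False))
        recon = reconstruct_volume(raw, tm, ReconOptions(align=False))
        inner = recon.data[3][48:-48, 48:-48]
        assert inner.std() / inner.mean() < 0.01

    def test_linear_in_phantom_density(self, optics):
        from mfsim import CameraConfig, EmitterSet, MultifocusConfig, rasterize_emitters, simulate_acquisition, simulate_widefield_zscan
        from mfsim.phantoms import DensityPhantom
        from mfsim.registration import calibrate_tile_map

        px = optics.px_sample
        pos = np.array([[20 * px, 40 * px, 0.0], [44 * px, 24 * px, 0.0]])
        ph = rasterize_emitters(EmitterSet(pos, brightness=5000.0),
                                (1, 64, 64), (132.0, px, px))
        mf = MultifocusConfig(tile_px=64)
        cam = CameraConfig(frame_px=(232, 232), offset=0.0)
        tm = calibrate_tile_map(
            simulate_widefield_zscan(ph, optics, mf, cam, n_steps=7,
                                     zstep_nm=264.0, noise=False))
        kw = dict(seed=0, noise=False)
        r1 = reconstruct_volume(
            simulate_acquisition(ph, IlluminationPattern(), optics, mf, cam, **kw),
            tm, ReconOptions(align=False))
        ph3 = DensityPhantom(3.0 * ph.volume, ph.voxel)
        r3 = reconstruct_volume(
            simulate_acquisition(ph3, IlluminationPattern(), optics, mf, cam, **kw),
            tm, ReconOptions(align=False))
        mask = r1.data > 0.05 * r1.data.max()
        ratio = r3.data[mask] / r1.data[mask]
        assert np.median(np.abs(ratio - 3.0)) < 0.03

    def test_widefield_acquisition_rejected(self, bead_phantom, optics, multifocus,
                                            camera, bead_tile_map):
        from mfsim import simulate_widefield_zscan

        scan = simulate_widefield_zscan(bead_phantom, optics, multifocus, camera,
                                        n_steps=3, seed=0)
        with pytest.raises(ReconstructionError):
            reconstruct_volume(scan, bead_tile_map)


class TestWidefieldAverage:
    def test_constant_frames_average_to_constant(self, optics, multifocus, camera,
                                                 bead_tile_map):
        from mfsim.mf_simulator import RawAcquisition, AcquisitionTiming

        frames = np.full((1, 1, 3, 5) + camera.shape, 150.0)
        raw = RawAcquisition(frames=frames, timing=AcquisitionTiming(),
                             optics=optics, pattern=IlluminationPattern(),
                             multifocus=multifocus, camera=camera)
        wf = widefield_average(raw, bead_tile_map)
        assert np.allclose(wf.data, 150.0 - camera.offset)

    def test_stripe_cancellation_and_mean_conservation(
        self, noiseless_bead_acquisition, bead_tile_map
    ):
        raw = noiseless_bead_acquisition
        wf = widefield_average(raw, bead_tile_map)
        grouped = _group_planes(raw, bead_tile_map, 0, 0)
        # direct-summation oracle for the mean
        assert wf.data.mean() == pytest.approx(grouped.mean(), rel=1e-12)
        # modulation cancels: per-plane widefield equals phase-mean for
        # every orientation separately to high accuracy
        for o in range(3):
            per_orient = grouped[:, o].mean(axis=1)
            assert np.max(np.abs(per_orient - wf.data)) < 1e-6 * wf.data.max()


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(1, 10, (5, 16, 16))
        psf = np.zeros((3, 5, 5))
        psf[1, 2, 2] = 1.0
        out = rl_deconvolve(vol, psf, iterations=7)
        assert np.allclose(out, vol, rtol=1e-6)

    def test_flux_conserved_within_half_percent(self, optics):
        from scipy.signal import fftconvolve

        rng = np.random.default_rng(1)
        truth = np.zeros((7, 32, 32))
        truth[3, 16, 16] = 100.0
        truth[4, 8, 20] = 60.0
        psf = generate_psf(optics, (5, 33, 33), (264.0, 64.5, 64.5)).data
        blurred = fftconvolve(truth, psf, mode="same")
        out = rl_deconvolve(blurred, psf, iterations=20)
        assert out.sum() == pytest.approx(blurred.sum(), rel=0.005)

    def test_sharpens_a_blurred_bead(self, optics):
        from scipy.signal import fftconvolve
        from mfsim import measure_fwhm

        truth = np.zeros((7, 49, 49))
        truth[3, 24, 24] = 1000.0
        psf = generate_psf(optics, (7, 49, 49), (264.0, 64.5, 64.5)).data
        blurred = fftconvolve(truth, psf, mode="same")
        pos = np.array([[24 * 64.5, 24 * 64.5, 3 * 264.0]])
        before = measure_fwhm(blurred, pos, (264.0, 64.5, 64.5))
        out = rl_deconvolve(blurred, psf, iterations=20)
        after = measure_fwhm(out, pos, (264.0, 64.5, 64.5))
        assert after.mean["x"] < before.mean["x"]
        assert after.mean["z"] < before.mean["z"]

    def test_negative_input_clamped_with_warning(self):
        vol = np.ones((3, 8, 8))
        vol[0, 0, 0] = -5.0
        psf = np.zeros((3, 3, 3))
        psf[1, 1, 1] = 1.0
        with pytest.warns(UserWarning, match="clamped"):
            rl_deconvolve(vol, psf, iterations=1)
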