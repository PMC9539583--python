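import numpy as np
import pytest
from scipy import stats

from ivimdnn.core import AcquisitionScheme, ParamRanges
from ivimdnn.phantom import (PhantomTemplate, SimulationGrid, _ellipse_mask,
                             add_rician_noise, generate_grid, generate_phantom,
                             sample_roi_params, SHEPP_LOGAN_ELLIPSES)


class TestTemplate:
    def test_six_disjoint_rois(self, template):
        labels = template.roi_labels
        assert sorted(np.unique(labels)) == [0, 1, 2, 3, 4, 5, 6]
        # inner ellipses must not overlap each other
        inner_masks = [_ellipse_mask(template.shape, *e)
                       for e in SHEPP_LOGAN_ELLIPSES[1:]]
        total = sum(m.sum() for m in inner_masks)
        union = np.any(inner_masks, axis=0).sum()
        assert total == union

    def test_background_is_label_zero(self, template):
        head = _ellipse_mask(template.shape, *SHEPP_LOGAN_ELLIPSES[0])
        assert np.all(template.roi_labels[~head] == 0)


class TestSampleRoiParams:
    def test_degenerate_range_returns_constant(self, rng):
        r = ParamRanges(D=(0.001, 0.001 + 1e-12), f=(0.2, 0.2 + 1e-12),
                        Dstar=(0.05, 0.05 + 1e-12))
        p = sample_roi_params(r, rng)
        assert p.D == pytest.approx(0.001) and p.f == pytest.approx(0.2)

    def test_uniform_moments_and_support(self, ranges, rng):
        """Empirical mean of D within 3 SE of the uniform mean (lo+hi)/2;
        every draw inside the default box."""
        triplets = [sample_roi_params(ranges, rng) for _ in range(20_000)]
        D = np.array([t.D for t in triplets])
        lo, hi = ranges.D
        se = (hi - lo) / np.sqrt(12 * D.size)
        assert abs(D.mean() - (lo + hi) / 2) < 3 * se
        assert all(ranges.contains(t) for t in triplets)


class TestRicianNoise:
    def test_infinite_snr_limit_is_identity(self, rng):
        s = np.linspace(0.1, 1.0, 50)
        out = add_rician_noise(s, snr=1e12, reference=np.ones(50), rng=rng)
        assert np.allclose(out, s, rtol=1e-6)

    def test_rayleigh_mean_on_zero_signal(self, rng):
        """S=0 voxels give Rayleigh magnitudes with mean sigma*sqrt(pi/2)."""
        n = 100_000
        sigma = 0.05
        out = add_rician_noise(np.zeros(n), snr=1.0 / sigma,
                               reference=np.ones(n), rng=rng)
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(n)
        assert abs(out.mean() - expected) < 3 * se

    def test_high_snr_bias_negligible(self, rng):
        out = add_rician_noise(np.ones(100_000), snr=100,
                               reference=np.ones(100_000), rng=rng)
        assert 0.999 < out.mean() < 1.002

    def test_output_nonnegative(self, rng):
        out = add_rician_noise(np.zeros(1000), snr=2, reference=np.ones(1000),
                               rng=rng)
        assert np.all(out >= 0)

    def test_rejects_nonpositive_snr(self, rng):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), snr=0, reference=np.ones(3), rng=rng)


class TestGeneratePhantom:
    def test_deterministic_given_seed(self, template, scheme, ranges):
        a = generate_phantom(template, scheme, ranges, 20, np.random.default_rng(5))
        b = generate_phantom(template, scheme, ranges, 20, np.random.default_rng(5))
        assert np.array_equal(a.noisy, b.noisy)
        assert np.array_equal(a.truth_D, b.truth_D)

    def test_noiseless_b0_channel_equals_b0_map(self, noisy_phantom):
        assert np.array_equal(noisy_phantom.noiseless[..., 0], noisy_phantom.b0_map)

    def test_roi_constant_truth_and_snr_homogeneity(self, noisy_phantom):
        inst = noisy_phantom
        for label in range(1, 7):
            m = inst.roi_labels == label
            assert np.unique(inst.truth_D[m]).size == 1
            assert np.unique(inst.b0_map[m]).size == 1
        fg = inst.foreground
        # applied Gaussian scale is exactly S0/SNR on every foreground voxel
        assert np.array_equal(inst.noise_sigma[fg], inst.b0_map[fg] / inst.snr)

    def test_background_pure_noise_and_zero_truth(self, noisy_phantom):
        bg = ~noisy_phantom.foreground
        assert np.all(noisy_phantom.noiseless[bg] == 0)
        assert np.all(noisy_phantom.truth_D[bg] == 0)
        assert np.all(noisy_phantom.noisy >= 0)

    def test_noiseless_lsq_recovers_roi_triplets(self, template, scheme, ranges):
        """Inversion oracle: fitting the noiseless stack returns each ROI's
        generating triplet to better than 1e-4 relative."""
        from ivimdnn.baseline import fit_voxel_lsq

        inst = generate_phantom(template, scheme, ranges, 50,
                                np.random.default_rng(11))
        for label, params in inst.roi_params.items():
            idx = np.argwhere(inst.roi_labels == label)[0]
            sig = inst.noiseless[idx[0], idx[1]]
            theta, ok = fit_voxel_lsq(sig, scheme)
            truth = np.array([params.D, params.f, params.Dstar])
            assert ok
            assert np.all(np.abs(theta - truth) / truth < 1e-4)


class TestGenerateGrid:
    def test_counts_and_split(self, template, scheme, ranges):
        grid = SimulationGrid(snr_levels=(10, 50), phantoms_per_snr=4, master_seed=3)
        out = list(generate_grid(grid, template, scheme, ranges))
        assert len(out) == 8
        tags = [t for t, _ in out]
        assert tags.count("train") == 4 and tags.count("test") == 4

    def test_reproducible_and_order_independent(self, template, scheme, ranges):
        grid = SimulationGrid(snr_levels=(10, 50), phantoms_per_snr=2, master_seed=9)
        full = {inst.seed: inst for _, inst in
                generate_grid(grid, template, scheme, ranges)}
        test_only = [inst for _, inst in
                     generate_grid(grid, template, scheme, ranges, split="test")]
        for inst in test_only:
            assert np.array_equal(inst.noisy, full[inst.seed].noisy)

    def test_roi_d_values_uniform(self, template, scheme, ranges):
        """Across a 100-phantom grid the ROI D draws pass a KS uniformity
        check at alpha = 0.01."""
        grid = SimulationGrid(snr_levels=(25,), phantoms_per_snr=100, master_seed=17)
        draws = []
        for _, inst in generate_grid(grid, template, scheme, ranges):
            draws.extend(p.D for p in inst.roi_params.values())
        lo, hi = ranges.D
        stat, p = stats.kstest((np.array(draws) - lo) / (hi - lo), "uniform")
        assert p > 0.01
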