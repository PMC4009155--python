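"""Kernel-layer unit and property tests: intensity estimation, Schoenberg
kernels, compositions, distances, Gram matrices and the size heuristic."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spikefield as sf
from spikefield.errors import DegenerateScaleError, WindowMismatchError
from spikefield.kernels import combine_modalities, modality_grams

from conftest import random_sample


def grid_intensity(times, T, tau, dt=0.001):
    """Independent gridded construction of the rectangular-smoothed intensity."""
    mids = np.arange(0, T, dt) + dt / 2
    lam = np.zeros_like(mids)
    for t in np.asarray(times):
        lam += ((mids >= t) & (mids < t + tau)) / tau
    return mids, lam


class TestEstimateIntensity:
    def test_empty_window_gives_zero(self):
        est = sf.estimate_intensity(sf.SpikeWindow([], 9.0), 9.0)
        assert est.integral() == 0.0
        assert np.all(est(np.linspace(0, 9, 50)) == 0.0)

    @pytest.mark.parametrize(
        "times, expected",
        [
            ([2.0], [(1.0, 0.0), (2.5, 1 / 9), (8.9, 1 / 9)]),
            ([2.0, 3.0], [(2.5, 1 / 9), (3.5, 2 / 9), (8.9, 2 / 9), (1.0, 0.0)]),
        ],
    )
    def test_hand_cases(self, times, expected):
        est = sf.estimate_intensity(sf.SpikeWindow(times, 9.0), 9.0)
        for t, v in expected:
            assert est(t) == pytest.approx(v, abs=1e-12)

    def test_matches_grid_construction(self, rng):
        for _ in range(20):
            times = np.sort(rng.uniform(0, 9, size=rng.integers(0, 5)))
            tau = rng.uniform(1.0, 12.0)
            est = sf.estimate_intensity(sf.SpikeWindow(times, 9.0), tau)
            mids, lam = grid_intensity(times, 9.0, tau)
            assert np.allclose(est(mids), lam, atol=1e-9)


class TestSpikeKernel:
    def test_self_similarity_is_one(self, spec, rng):
        w = sf.SpikeWindow(np.sort(rng.uniform(0, 9, 3)), 9.0)
        assert sf.spike_kernel(w, w, spec) == 1.0

    def test_both_empty_is_one(self, spec):
        a, b = sf.SpikeWindow([], 9.0), sf.SpikeWindow([], 9.0)
        assert sf.spike_kernel(a, b, spec) == 1.0

    def test_single_spike_closed_form(self):
        # intensity-difference integral for {2} vs {5} with full-window
        # smoothing is 3 * (1/81) = 1/27
        spec = sf.CompositeKernelSpec(
            sigma_s=np.sqrt(1 / 27), sigma_x=1.0, smoothing_width=9.0
        )
        a, b = sf.SpikeWindow([2.0], 9.0), sf.SpikeWindow([5.0], 9.0)
        assert sf.spike_kernel(a, b, spec) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_mismatched_support_raises(self, spec):
        with pytest.raises(WindowMismatchError):
            sf.spike_kernel(sf.SpikeWindow([], 9.0), sf.SpikeWindow([], 10.0), spec)

    def test_empty_vs_nonempty_below_one(self, spec):
        a, b = sf.SpikeWindow([], 9.0), sf.SpikeWindow([4.0], 9.0)
        assert 0.0 < sf.spike_kernel(a, b, spec) < 1.0


class TestSumKernels:
    def test_multiunit_cases(self):
        spec_u = sf.CompositeKernelSpec(
            sigma_s=np.sqrt(1 / 27), sigma_x=1.0, smoothing_width=9.0,
            normalize_channels=False,
        )
        same = sf.SpikeWindow([1.0], 9.0)
        a = sf.MultiunitSpikeWindow((same, sf.SpikeWindow([2.0], 9.0)))
        b = sf.MultiunitSpikeWindow((same, sf.SpikeWindow([5.0], 9.0)))
        unnorm = sf.multiunit_spike_kernel(a, b, spec_u)
        assert unnorm == pytest.approx(1 + np.exp(-1), rel=1e-12)
        spec_n = sf.CompositeKernelSpec(
            sigma_s=np.sqrt(1 / 27), sigma_x=1.0, smoothing_width=9.0,
        )
        assert sf.multiunit_spike_kernel(a, b, spec_n) == pytest.approx(
            (1 + np.exp(-1)) / 2, rel=1e-12
        )

    def test_unit_count_mismatch(self, spec):
        a = sf.MultiunitSpikeWindow((sf.SpikeWindow([], 9.0),))
        b = sf.MultiunitSpikeWindow((sf.SpikeWindow([], 9.0),) * 2)
        with pytest.raises(WindowMismatchError):
            sf.multiunit_spike_kernel(a, b, spec)

    def test_lfp_hand_cases(self):
        spec2 = sf.CompositeKernelSpec(sigma_s=1.0, sigma_x=np.sqrt(2.0))
        a, b = sf.LFPWindow([1.0, 1.0], 1.0), sf.LFPWindow([0.0, 0.0], 1.0)
        assert sf.lfp_kernel(a, b, spec2) == pytest.approx(np.exp(-1), rel=1e-12)
        spec1 = sf.CompositeKernelSpec(sigma_s=1.0, sigma_x=1.0)
        c, d = sf.LFPWindow([1.0, 0.0], 1.0), sf.LFPWindow([0.0, 1.0], 1.0)
        assert sf.lfp_kernel(c, d, spec1) == pytest.approx(np.exp(-2), rel=1e-12)

    def test_multichannel_sum_and_normalization(self):
        spec_u = sf.CompositeKernelSpec(
            sigma_s=1.0, sigma_x=np.sqrt(2.0), normalize_channels=False
        )
        a = sf.MultichannelLFPWindow(
            (sf.LFPWindow([1.0, 1.0], 1.0), sf.LFPWindow([1.0, 1.0], 1.0))
        )
        b = sf.MultichannelLFPWindow(
            (sf.LFPWindow([0.0, 0.0], 1.0), sf.LFPWindow([0.0, 0.0], 1.0))
        )
        assert sf.multichannel_lfp_kernel(a, b, spec_u) == pytest.approx(
            2 * np.exp(-1), rel=1e-12
        )
        spec_n = sf.CompositeKernelSpec(sigma_s=1.0, sigma_x=np.sqrt(2.0))
        assert sf.multichannel_lfp_kernel(a, b, spec_n) == pytest.approx(
            np.exp(-1), rel=1e-12
        )


class TestJointKernel:
    def test_product_equals_factor_product(self, spec, sample_factory):
        a, b = sample_factory(2)
        ks = sf.multiunit_spike_kernel(a.spikes, b.spikes, spec)
        kx = sf.multichannel_lfp_kernel(a.lfp, b.lfp, spec)
        assert sf.joint_kernel(a, b, spec) == ks * kx  # bit-exact identity

    def test_rules(self, spec, sample_factory):
        a, b = sample_factory(2)
        ks = sf.multiunit_spike_kernel(a.spikes, b.spikes, spec)
        kx = sf.multichannel_lfp_kernel(a.lfp, b.lfp, spec)
        from dataclasses import replace

        assert sf.joint_kernel(a, b, replace(spec, modality_rule="sum")) == ks + kx
        assert sf.joint_kernel(a, b, replace(spec, modality_rule="spikes_only")) == ks
        assert sf.joint_kernel(a, b, replace(spec, modality_rule="lfp_only")) == kx

    def test_strict_similarity(self, spec, sample_factory):
        """A vanishing LFP factor forces the product to vanish regardless of
        how similar the spike trains are."""
        a = sample_factory(1)
        big = sf.MultichannelLFPWindow(
            tuple(sf.LFPWindow(c.samples + 100.0, 1.0) for c in a.lfp.channels)
        )
        b = sf.MultiscaleSample(a.spikes, big)
        kx = sf.multichannel_lfp_kernel(a.lfp, b.lfp, spec)
        assert kx < 1e-8
        assert sf.joint_kernel(a, b, spec) < 1e-8


class TestRKHSDistance:
    @pytest.mark.parametrize(
        "kaa, kbb, kab, expected",
        [
            (1.0, 1.0, 1.0, 0.0),
            (1.0, 1.0, 0.0, np.sqrt(2.0)),
            (2.0, 2.0, 1.367879, np.sqrt(1.264242)),
        ],
    )
    def test_values(self, kaa, kbb, kab, expected):
        assert sf.rkhs_distance(kaa, kbb, kab) == pytest.approx(expected, abs=1e-6)

    def test_roundoff_clipped(self):
        assert sf.rkhs_distance(1.0, 1.0, 1.0 + 1e-15) == 0.0

    @given(st.floats(0.0, 1.0))
    def test_normalized_shortcut(self, k):
        assert sf.rkhs_distance(1.0, 1.0, k) == pytest.approx(
            np.sqrt(2 - 2 * k), abs=1e-12
        )


class TestSymmetryProperties:
    def test_symmetry_and_self_similarity(self, spec, rng):
        from dataclasses import replace

        for _ in range(20):
            a, b = random_sample(rng), random_sample(rng)
            for rule in ("product", "sum", "spikes_only", "lfp_only"):
                rspec = replace(spec, modality_rule=rule)
                assert sf.joint_kernel(a, b, rspec) == pytest.approx(
                    sf.joint_kernel(b, a, rspec), abs=1e-12
                )
                self_sim = sf.joint_kernel(a, a, rspec)
                expected = 2.0 if rule == "sum" else 1.0
                assert self_sim == pytest.approx(expected, abs=1e-12)


class TestGram:
    def test_identical_pair(self, spec, sample_factory):
        s = sample_factory(1)
        G = sf.gram_matrix([s, s], spec)
        assert np.allclose(G, 1.0, atol=1e-12)

    def test_single_sample(self, spec, sample_factory):
        G = sf.gram_matrix([sample_factory(1)], spec)
        assert G.shape == (1, 1) and G[0, 0] == pytest.approx(1.0)

    def test_psd_all_rules(self, spec, rng):
        from dataclasses import replace

        samples = [random_sample(rng) for _ in range(50)]
        for rule in ("product", "sum", "spikes_only", "lfp_only"):
            G = sf.gram_matrix(samples, replace(spec, modality_rule=rule))
            assert np.allclose(G, G.T)
            assert np.linalg.eigvalsh(G).min() >= -1e-10

    def test_batch_matches_scalar_path(self, spec, rng):
        samples = [random_sample(rng) for _ in range(6)]
        G = sf.gram_matrix(samples, spec)
        for i in range(6):
            for j in range(6):
                assert G[i, j] == pytest.approx(
                    sf.joint_kernel(samples[i], samples[j], spec), abs=1e-12
                )


class TestKernelSizeHeuristic:
    def test_single_pair_lfp(self):
        a = sf.LFPWindow([2.0, 0.0], 1.0)   # squared distance 4
        b = sf.LFPWindow([0.0, 0.0], 1.0)
        assert sf.kernel_size_heuristic([a, b], "lfp") == pytest.approx(2.0)

    def test_three_sample_mean(self):
        # pairwise squared distances {1, 1, 4} -> sigma = sqrt(2)
        ws = [
            sf.LFPWindow([0.0], 1.0),
            sf.LFPWindow([1.0], 1.0),
            sf.LFPWindow([-1.0], 1.0),
        ]
        assert sf.kernel_size_heuristic(ws, "lfp") == pytest.approx(np.sqrt(2.0))

    def test_identical_samples_degenerate(self):
        w = sf.LFPWindow([1.0, 2.0], 1.0)
        with pytest.raises(DegenerateScaleError):
            sf.kernel_size_heuristic([w, w], "lfp")

    def test_batch_matches_window_path(self, rng):
        samples = [random_sample(rng, n_units=2, n_channels=1) for _ in range(8)]
        sig_batch = sf.kernel_size_heuristic(samples, "lfp")
        lfps = [s.lfp for s in samples]
        assert sig_batch == pytest.approx(
            sf.kernel_size_heuristic(lfps, "lfp"), rel=1e-9
        )

    def test_spike_modality(self, rng):
        samples = [random_sample(rng) for _ in range(6)]
        sig = sf.kernel_size_heuristic(samples, "spikes")
        assert sig > 0


def test_spec_json_roundtrip():
    spec = sf.CompositeKernelSpec(
        sigma_s=0.4, sigma_x=2.0, smoothing_width=9.0,
        normalize_channels=False, modality_rule="sum",
    )
    doc = spec.to_json()
    assert json.loads(doc)["smoothing_width_ms"] == 9.0
    assert sf.CompositeKernelSpec.from_json(doc) == spec


def test_shared_modality_blocks_match_rules(spec, rng):
    samples = [random_sample(rng) for _ in range(5)]
    Ks, Kx = modality_grams(samples, None, spec)
    from dataclasses import replace
    from spikefield.kernels import pairwise_kernel

    for rule in ("product", "sum", "spikes_only", "lfp_only"):
        assert np.array_equal(
            combine_modalities(Ks, Kx, rule),
            pairwise_kernel(samples, None, replace(spec, modality_rule=rule)),
        )
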