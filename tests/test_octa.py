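"""Speckle-variance estimator and angiogram construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from octasv.io import OCTVolume
from octasv.octa import SVConfig, assemble_neighbor_stack, construct_octa, speckle_variance


def two_pass_variance(stack, ddof=0):
    """Independent per-pixel two-pass oracle."""
    stack = np.asarray(stack, dtype=np.float64)
    c = stack.shape[0]
    out = np.zeros(stack.shape[1:])
    for i in range(stack.shape[1]):
        for j in range(stack.shape[2]):
            vals = stack[:, i, j]
            mean = sum(vals) / c
            out[i, j] = sum((v - mean) ** 2 for v in vals) / (c - ddof)
    return out


class TestSpeckleVariance:
    def test_identical_frames_zero(self):
        frames = [np.full((8, 8), 3.0)] * 4
        assert not speckle_variance(frames).any()

    def test_hand_computed_two_frame_values(self):
        frames = [np.zeros((4, 4)), np.full((4, 4), 2.0)]
        np.testing.assert_allclose(speckle_variance(frames, "population"), 1.0)
        np.testing.assert_allclose(speckle_variance(frames, "sample"), 2.0)

    def test_matches_two_pass_oracle(self, rng):
        stack = rng.random((4, 8, 8))
        np.testing.assert_allclose(speckle_variance(stack, "population"),
                                   two_pass_variance(stack, 0), atol=1e-12)
        np.testing.assert_allclose(speckle_variance(stack, "sample"),
                                   two_pass_variance(stack, 1), atol=1e-12)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            speckle_variance([np.zeros((4, 4))])

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.float64, (3, 6, 6), elements=st.floats(0, 100)),
           st.permutations(range(3)))
    def test_permutation_invariance(self, stack, perm):
        np.testing.assert_allclose(speckle_variance(stack),
                                   speckle_variance(stack[list(perm)]), atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.float64, (4, 5, 5), elements=st.floats(0, 50)),
           st.floats(0.1, 10))
    def test_quadratic_intensity_scaling(self, stack, a):
        np.testing.assert_allclose(speckle_variance(a * stack),
                                   a**2 * speckle_variance(stack), rtol=1e-9, atol=1e-9)


class TestConstructOcta:
    def test_static_volume_temporal_sv_zero(self):
        vol = OCTVolume(np.broadcast_to(np.random.default_rng(0).random((2, 1, 8, 8)),
                                        (2, 4, 8, 8)).copy())
        angio = construct_octa(vol, SVConfig(mode="temporal", n_scans=4))
        assert np.allclose(angio.data, 0.0)

    def test_temporal_uses_first_n_repeats(self, rng):
        data = rng.random((2, 4, 8, 8))
        vol = OCTVolume(data)
        angio = construct_octa(vol, SVConfig(mode="temporal", n_scans=2))
        np.testing.assert_allclose(angio.data, np.var(data[:, :2], axis=1))
        assert angio.provenance == "temporal_sv" and angio.n_scans == 2

    def test_flow_contrast_on_phantom(self, small_phantom):
        _, vol, truth = small_phantom
        angio = construct_octa(vol, SVConfig(mode="temporal", n_scans=4))
        static = (truth.reflectance > 0.1) & ~truth.flow_mask
        assert angio.data[truth.flow_mask].mean() > 5 * angio.data[static].mean()

    def test_spatial_3n_on_three_frames_equals_direct_sv(self, rng):
        data = rng.random((3, 2, 8, 8))
        vol = OCTVolume(data)
        angio = construct_octa(vol, SVConfig(mode="spatial", n_scans=3, edge_policy="valid"))
        frames = data.mean(axis=1)
        np.testing.assert_allclose(angio.data[0], speckle_variance(frames))
        assert angio.data.shape[0] == 1  # S - (n-1)

    def test_spatial_reflect_preserves_length(self, rng):
        vol = OCTVolume(rng.random((5, 2, 8, 8)))
        for n in (2, 3, 4):
            angio = construct_octa(vol, SVConfig(mode="spatial", n_scans=n))
            assert angio.data.shape[0] == 5

    def test_spatial_single_repeat_option(self, rng):
        data = rng.random((4, 3, 8, 8))
        vol = OCTVolume(data)
        angio = construct_octa(vol, SVConfig(mode="spatial", n_scans=2,
                                             edge_policy="valid", single_repeat=True))
        np.testing.assert_allclose(angio.data[0],
                                   speckle_variance(data[:2, 0]))

    def test_n_exceeding_axis_rejected(self, rng):
        vol = OCTVolume(rng.random((2, 2, 8, 8)))
        with pytest.raises(ValueError):
            construct_octa(vol, SVConfig(mode="temporal", n_scans=4))
        with pytest.raises(ValueError):
            construct_octa(vol, SVConfig(mode="spatial", n_scans=3))


class TestNeighborStack:
    def test_interior_channels_are_neighbor_frames(self, rng):
        data = rng.random((5, 2, 8, 8))
        vol = OCTVolume(data)
        st_ = assemble_neighbor_stack(vol, 2, C=3)
        frames = data.mean(axis=1)
        for c, s in enumerate((1, 2, 3)):
            np.testing.assert_allclose(st_.data[:, :, c], frames[s])

    def test_edge_policies_at_first_frame(self, rng):
        data = rng.random((4, 1, 8, 8))
        vol = OCTVolume(data)
        frames = data[:, 0]
        reflect = assemble_neighbor_stack(vol, 0, C=3, edge_policy="reflect")
        np.testing.assert_allclose(reflect.data[:, :, 0], frames[1])  # (1, 0, 1)
        clamp = assemble_neighbor_stack(vol, 0, C=3, edge_policy="clamp")
        np.testing.assert_allclose(clamp.data[:, :, 0], frames[0])  # (0, 0, 1)
        np.testing.assert_allclose(clamp.data[:, :, 2], frames[1])

    def test_single_channel_is_collapsed_frame(self, rng):
        data = rng.random((3, 4, 8, 8))
        vol = OCTVolume(data)
        st_ = assemble_neighbor_stack(vol, 1, C=1)
        np.testing.assert_allclose(st_.data[:, :, 0], data[1].mean(axis=0))

    def test_out_of_range_index(self, rng):
        vol = OCTVolume(rng.random((3, 1, 8, 8)))
        with pytest.raises(IndexError):
            assemble_neighbor_stack(vol, 3, C=3)
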