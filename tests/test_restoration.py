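import numpy as np
import pytest

from nfmo import (
    AlternationState,
    NoiseSpec,
    RestorationConfig,
    ValidationError,
    build_workspace,
    denoise,
    dilate_fill,
    inject,
    make_worked_example,
    mirror_pad,
    nested_restore,
    psnr,
    replace_center,
    restore_pixel,
)
from nfmo.detection import NoiseMask
from nfmo.restoration import CLEAN, STAGE1, STAGE2, UNRESTORED, _lower_median

from _reference import denoise_ref, lower_median, restore_pixel_ref

CFG = RestorationConfig()


def _padded_fixture(n=24, density=0.6, seed=0):
    rng = np.random.default_rng(seed)
    plane = rng.integers(0, 256, size=(n, n)).astype(np.uint8)
    mask = rng.random((n, n)) < density
    return (
        mirror_pad(plane.astype(np.int64), CFG.ms),
        np.pad(mask, CFG.ms, mode="reflect"),
    )


def test_config_validation():
    with pytest.raises(ValidationError):
        RestorationConfig(sw1=6)
    with pytest.raises(ValidationError):
        RestorationConfig(sw2=1)
    with pytest.raises(ValidationError):
        RestorationConfig(structuring_element=((0, 0), (0, 1)))
    assert RestorationConfig().ms == 5


def test_workspace_all_clean_neighbours():
    padded, _ = _padded_fixture()
    mask = np.zeros_like(padded, dtype=bool)
    mask[12, 12] = True
    ws = build_workspace(padded, mask, (12, 12), CFG)
    counts = ws.state_counts()
    assert counts["clean"] == 48
    assert counts["unrestored"] == 0


def test_workspace_at_image_corner_uses_mirror():
    """A centre at the original (0, 0) — padded (Ms, Ms) — is fully in
    bounds thanks to the mirror margin."""
    padded, maskp = _padded_fixture()
    ws = build_workspace(padded, maskp, (CFG.ms, CFG.ms), CFG)
    assert ws.values.shape == (7, 7)
    with pytest.raises(ValidationError):
        build_workspace(padded, maskp, (1, 1), CFG)  # window would overrun


def test_worked_example_walkthrough():
    """The 3-clean-of-48 neighbourhood: nested filtering restores exactly the
    neighbours whose secondary window reaches a clean pixel, the dilation
    completes the rest, and the final value is an observed intensity."""
    ex = make_worked_example()
    ws = build_workspace(ex.plane, ex.mask, ex.center, ex.config)
    counts = ws.state_counts()
    assert counts["clean"] == 3
    assert counts["unrestored"] == 45

    nested_restore(ws, ex.plane, ex.mask, ex.config)
    counts = ws.state_counts()
    assert counts["stage1"] == ex.expected_counts["stage1"]
    assert 0 < counts["stage1"] < 45  # strict subset restored by stage 1

    dilate_fill(ws, ex.config)
    counts = ws.state_counts()
    assert counts == {"clean": 3, **{k: ex.expected_counts[k] for k in ("stage1", "stage2")},
                      "unrestored": 0}

    value = replace_center(ws)
    assert value in (228, 231, 234)  # only observed clean intensities exist


def test_nested_restore_takes_singleton_clean_value():
    padded = np.zeros((17, 17), dtype=np.int64)
    mask = np.ones((17, 17), dtype=bool)
    padded[3, 5] = 77  # only clean pixel, inside the secondary window of (5, 5)
    mask[3, 5] = False
    ws = build_workspace(padded, mask, (8, 8), CFG)
    nested_restore(ws, padded, mask, CFG)
    assert ws.states[0, 0] == STAGE1
    assert ws.values[0, 0] == 77


def test_nested_restore_never_uses_same_pass_results():
    """Stage-1 estimates come from the original plane only: a neighbour whose
    secondary window contains restored-but-not-clean pixels stays unrestored."""
    padded = np.zeros((17, 17), dtype=np.int64)
    mask = np.ones((17, 17), dtype=bool)
    padded[3, 3] = 200  # reaches neighbour (5, 5) but not (5, 9)
    mask[3, 3] = False
    ws = build_workspace(padded, mask, (8, 8), CFG)
    nested_restore(ws, padded, mask, CFG)
    assert ws.states[0, 0] == STAGE1
    assert ws.states[0, 4] == UNRESTORED  # (5, 9): nearest clean is Chebyshev 6 away


def test_dilation_picks_maximum_first():
    """Candidates {231, 234} under the starting alternation give 234."""
    padded = np.full((17, 17), 200, dtype=np.int64)
    mask = np.zeros((17, 17), dtype=bool)
    mask[8, 8] = True  # centre
    mask[5, 5] = True  # first unrestored neighbour in raster order
    padded[5, 6] = 231
    padded[6, 5] = 234
    ws = build_workspace(padded, mask, (8, 8), CFG)
    dilate_fill(ws, CFG)
    assert ws.states[0, 0] == STAGE2
    assert ws.values[0, 0] == 234


def test_alternation_state_toggles():
    alt = AlternationState()
    assert alt.pick([231, 234]) == 234
    assert alt.pick([231, 234]) == 231
    assert alt.pick([10, 20]) == 20


def test_dilation_with_empty_useful_set_leaves_all_degenerate():
    padded = np.zeros((17, 17), dtype=np.int64)
    mask = np.ones((17, 17), dtype=bool)
    ws = build_workspace(padded, mask, (8, 8), CFG)
    dilate_fill(ws, CFG)
    assert ws.degenerate_positions == 48
    assert replace_center(ws) == int(padded[8, 8])  # degenerate policy: keep


def test_single_gap_filled_with_maximum_of_clean_neighbours():
    padded = np.full((17, 17), 100, dtype=np.int64)
    mask = np.zeros((17, 17), dtype=bool)
    mask[8, 8] = True
    mask[6, 6] = True  # local (1, 1): all four B-neighbours clean
    padded[5, 6] = 111
    padded[7, 6] = 117
    padded[6, 5] = 113
    padded[6, 7] = 115
    ws = build_workspace(padded, mask, (8, 8), CFG)
    dilate_fill(ws, CFG)
    assert ws.values[1, 1] == 117  # maximum, alternation at its initial state


def test_replace_center_conventions():
    padded = np.full((17, 17), 42, dtype=np.int64)
    mask = np.zeros((17, 17), dtype=bool)
    mask[8, 8] = True
    ws = build_workspace(padded, mask, (8, 8), CFG)
    assert replace_center(ws) == 42  # all neighbours equal

    values = np.arange(1, 50).reshape(7, 7)
    ws.values = values.astype(np.int64)
    ws.values[3, 3] = 999  # centre value must not participate
    states = np.full((7, 7), CLEAN, dtype=np.uint8)
    states[3, 3] = UNRESTORED
    ws.states = states
    # neighbours are {1..49} minus the centre entry; lower median of 48 values
    remaining = sorted(set(range(1, 50)) - {int(values[3, 3])})
    assert replace_center(ws) == remaining[(48 - 1) // 2]


@pytest.mark.parametrize("seed", range(5))
def test_replace_center_matches_sorting_oracle(seed):
    rng = np.random.default_rng(seed)
    padded = rng.integers(0, 256, size=(17, 17)).astype(np.int64)
    mask = np.zeros((17, 17), dtype=bool)
    mask[8, 8] = True
    ws = build_workspace(padded, mask, (8, 8), CFG)
    neighbours = [int(padded[r, c]) for r in range(5, 12) for c in range(5, 12)
                  if (r, c) != (8, 8)]
    assert replace_center(ws) == lower_median(neighbours)


def test_lower_median_convention():
    assert _lower_median(np.arange(1, 49)) == 24
    assert _lower_median(np.array([5])) == 5


def test_denoise_empty_mask_is_identity(random_image):
    mask = NoiseMask(
        location=np.zeros(random_image.shape[:2], dtype=bool),
        channel=np.zeros(random_image.shape, dtype=bool),
    )
    out, report = denoise(random_image, mask)
    assert np.array_equal(out, random_image)
    assert report.flagged == 0


def test_single_corrupted_pixel_on_constant_background():
    data = np.full((16, 16, 3), 128, dtype=np.uint8)
    noisy = data.copy()
    noisy[7, 7, 2] = 255
    channel = np.zeros(data.shape, dtype=bool)
    channel[7, 7, 2] = True
    mask = NoiseMask(location=channel.any(axis=2), channel=channel)
    out, report = denoise(noisy, mask)
    assert out[7, 7, 2] == 128
    assert np.array_equal(out, data)
    assert report.restored_centers == 1


def test_unflagged_entries_never_modified(random_image):
    noisy, truth = inject(random_image, NoiseSpec(0.5, seed=3))
    out, _ = denoise(noisy, truth)
    assert np.array_equal(out[~truth.channel], noisy[~truth.channel])


def test_engine_matches_public_per_pixel_ops():
    """The compiled whole-image path equals composing the public per-pixel
    operations in an arbitrary order — i.e. results are order-independent."""
    rng = np.random.default_rng(17)
    data = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
    noisy, truth = inject(data, NoiseSpec(0.6, seed=18))
    out, _ = denoise(noisy, truth)
    for ch in range(3):
        padded = mirror_pad(noisy[:, :, ch].astype(np.int64), CFG.ms)
        maskp = np.pad(truth.channel[:, :, ch], CFG.ms, mode="reflect")
        rs, cs = np.nonzero(truth.channel[:, :, ch])
        order = rng.permutation(rs.size)  # any processing order
        for idx in order:
            r, c = int(rs[idx]), int(cs[idx])
            value, _ws = restore_pixel(padded, maskp, (r + CFG.ms, c + CFG.ms), CFG)
            assert out[r, c, ch] == value


@pytest.mark.parametrize("density", [0.3, 0.9])
def test_denoise_matches_naive_reference(density):
    rng = np.random.default_rng(int(density * 10))
    data = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
    noisy, truth = inject(data, NoiseSpec(density, seed=21))
    out, _ = denoise(noisy, truth)
    expected = denoise_ref(noisy, truth.channel)
    assert np.array_equal(out, expected)


def test_high_density_restoration_improves_psnr_and_completes():
    rng = np.random.default_rng(30)
    data = np.full((24, 24, 3), 0, dtype=np.uint8)
    data[:, :, 0] = rng.integers(100, 200, size=(24, 24))
    data[:, :, 1] = data[:, :, 0]
    data[:, :, 2] = data[:, :, 0] // 2
    noisy, truth = inject(data, NoiseSpec(0.9, seed=31))
    out, report = denoise(noisy, truth)
    assert psnr(data, out) > psnr(data, noisy)
    # degenerate centres are exactly those with no clean value within the
    # combined reach Ms (checked by brute force on the padded mask)
    expected_degenerate = 0
    for ch in range(3):
        maskp = np.pad(truth.channel[:, :, ch], CFG.ms, mode="reflect")
        rs, cs = np.nonzero(truth.channel[:, :, ch])
        for r, c in zip(rs + CFG.ms, cs + CFG.ms):
            reach = maskp[r - CFG.ms : r + CFG.ms + 1, c - CFG.ms : c + CFG.ms + 1]
            if reach.all():
                expected_degenerate += 1
    assert report.unrestored_centers == expected_degenerate


def test_restore_pixel_matches_literal_reference():
    padded, maskp = _padded_fixture(n=20, density=0.7, seed=41)
    for center in [(7, 7), (5, 5), (14, 19), (10, 12)]:
        value, _ = restore_pixel(padded, maskp, center, CFG)
        expected, _ = restore_pixel_ref(padded, maskp, *center)
        assert value == expected


def test_mask_shape_mismatch_rejected(random_image):
    bad = NoiseMask(location=np.zeros((4, 4), dtype=bool), channel=np.zeros((4, 4, 3), dtype=bool))
    with pytest.raises(ValidationError):
        denoise(random_image, bad)
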